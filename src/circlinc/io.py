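"""Readers and writers for the pipeline's plain-text interchange formats.

Counts are genes x samples TSV (first column gene ID, header = sample IDs);
sample metadata is a two-column TSV (sample ID, group in {sPTB, term}); gene
sets use the tab-separated GMT convention (name, description, members);
planted truth round-trips through JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import PlantedTruth
from .types import CountMatrix, GeneSetCollection, ValidationError


def write_counts(cm: CountMatrix, counts_path: str | Path, meta_path: str | Path) -> None:
    df = cm.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(counts_path, sep="\t")
    meta = pd.DataFrame({"sample_id": cm.sample_ids, "group": cm.group.to_numpy()})
    meta.to_csv(meta_path, sep="\t", index=False)


def read_counts(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError(f"{counts_path}: non-integer counts")
        df = df.round().astype(np.int64)
    meta = pd.read_csv(meta_path, sep="\t")
    if list(meta.columns[:2]) != ["sample_id", "group"]:
        raise ValidationError(f"{meta_path}: expected columns sample_id, group")
    if meta["sample_id"].duplicated().any():
        raise ValidationError(f"{meta_path}: duplicate sample IDs")
    group = pd.Series(meta["group"].to_numpy(), index=meta["sample_id"].to_numpy())
    missing = set(df.columns) - set(group.index)
    if missing:
        raise ValidationError(f"{meta_path}: no group for samples {sorted(missing)}")
    return CountMatrix(counts=df, group=group)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in sets.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{line_no}: GMT line needs >= 3 fields")
            name, desc, *members = parts
            if name in sets:
                raise ValidationError(f"{path}:{line_no}: duplicated set name {name!r}")
            sets[name] = (desc, [m for m in members if m])
    return GeneSetCollection(sets=sets)


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    obj = {
        "de_genes": dict(sorted(truth.de_genes.items())),
        "planted_circadian_lincRNAs": sorted(truth.planted_circadian_lincRNAs),
        "clock_effect_directions": dict(sorted(truth.clock_effect_directions.items())),
        "correlation_strength": truth.correlation_strength,
    }
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> PlantedTruth:
    obj = json.loads(Path(path).read_text())
    return PlantedTruth(
        de_genes=obj["de_genes"],
        planted_circadian_lincRNAs=set(obj["planted_circadian_lincRNAs"]),
        clock_effect_directions=obj["clock_effect_directions"],
        correlation_strength=obj["correlation_strength"],
    )


def read_symbol_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
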