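"""Readers and writers for the pipeline's plain-text formats.

Everything is TSV (gene identifiers and annotations may contain commas)
except gene sets, which use the standard GMT layout: one set per line,
``name <tab> description <tab> member1 <tab> member2 ...``.  Writers are
loss-free inverses of the readers on valid data.  Every CLI run also
writes a JSON manifest (effective config, seeds, package version and
SHA-256 input checksums) sufficient to re-execute the run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneSetCollection, ModuleDefinition, validate_stats

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_counts",
    "write_counts",
    "read_stats",
    "write_stats",
    "read_modules",
    "write_modules",
    "write_manifest",
]


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file.

    Duplicate members within a set are dropped with a warning; duplicate
    set names or lines with fewer than three fields are errors naming the
    line.
    """
    sets: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name, desc, members = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            if len(set(members)) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: duplicate members in set {name!r} deduplicated",
                    stacklevel=2,
                )
            sets[name] = members
            provenance[name] = desc or "custom"
    return GeneSetCollection(sets, provenance)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            desc = collection.provenance.get(name, "custom")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")


def read_counts(path, metadata_path) -> CountMatrix:
    """Read a gene x sample count TSV plus its sample-metadata TSV.

    The count file's first column is the gene id.  Metadata needs columns
    sample, cohort, group, age, gender, tms.  Non-integer counts and
    samples missing from the metadata are errors naming the culprit.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t").set_index("sample")
    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise ValueError(f"sample {missing[0]!r} in counts is missing from metadata")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        frac, _ = np.modf(values.astype(float))
        if np.any(frac != 0):
            g, s = np.argwhere(frac != 0)[0]
            raise ValueError(
                f"non-integer count {counts.iat[g, s]!r} for gene "
                f"{counts.index[g]!r} in sample {counts.columns[s]!r}"
            )
    return CountMatrix(counts, meta)


def write_counts(cm: CountMatrix, path, metadata_path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene")
    cm.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


def read_stats(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="gene", float_precision="round_trip")
    table.index = table.index.astype(str)
    from .containers import STATS_COLUMNS

    for col in STATS_COLUMNS:
        if col in table.columns:
            table[col] = table[col].astype(float)
    return validate_stats(table)


def write_stats(table: pd.DataFrame, path) -> None:
    # %.17g keeps doubles exact, so write -> read is the identity
    validate_stats(table).to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_modules(path) -> list[ModuleDefinition]:
    """Read module definitions from a long-format TSV.

    Columns: module, gene, and optionally kME, annotation, region, hd_cor
    (annotation/region/hd_cor are per-module; the first row's value wins).
    """
    df = pd.read_csv(path, sep="\t", dtype={"module": str, "gene": str},
                     float_precision="round_trip")
    if "module" not in df.columns or "gene" not in df.columns:
        raise ValueError("module TSV needs 'module' and 'gene' columns")
    out = []
    for mod, sub in df.groupby("module", sort=True):
        kme_series = None
        if "kME" in sub.columns and sub["kME"].notna().any():
            kme_series = pd.Series(
                sub["kME"].to_numpy(dtype=float), index=sub["gene"].tolist()
            )
        first = sub.iloc[0]
        hd_cor = first.get("hd_cor")
        out.append(
            ModuleDefinition(
                module_id=str(mod),
                genes=tuple(sub["gene"]),
                kme=kme_series,
                annotation=(None if pd.isna(first.get("annotation", np.nan)) else str(first["annotation"])),
                region=(None if pd.isna(first.get("region", np.nan)) else str(first["region"])),
                hd_cor=(None if hd_cor is None or pd.isna(hd_cor) else float(hd_cor)),
            )
        )
    return out


def write_modules(modules: list[ModuleDefinition], path) -> None:
    rows = []
    for m in modules:
        for g in m.genes:
            rows.append(
                {
                    "module": m.module_id,
                    "gene": g,
                    "kME": (np.nan if m.kme is None or g not in m.kme.index else m.kme[g]),
                    "annotation": m.annotation,
                    "region": m.region,
                    "hd_cor": m.hd_cor,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, inputs: list = (), outputs: list = ()) -> None:
    """Write a reproducibility manifest next to a run's outputs."""
    from . import __version__

    manifest = {
        "package": "dgsea",
        "version": __version__,
        "config": config,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        "outputs": [str(p) for p in outputs],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
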