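"""File formats: TSV/CSV tables, MatrixMarket counts, BED intervals, JSON/YAML.

Compositions are stored as a sparse MatrixMarket file plus row (sample) and
column (subcluster) TSV sidecars; BED files are written 0-based half-open;
MatrixMarket indices are 1-based per the standard (handled by scipy).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .datatypes import CompositionTable
from .atac import GenomicInterval


class ParseError(ValueError):
    """Malformed input file; message carries the offending line when known."""


# -- cohort ---------------------------------------------------------------

def write_cohort(cohort, path: str | Path) -> None:
    frame = cohort.frame().copy()
    frame["regions"] = [",".join(cohort.regions[d]) for d in frame.index]
    frame.to_csv(path, sep="\t")


def read_cohort_frame(path: str | Path) -> pd.DataFrame:
    """Read a cohort TSV back as a covariate table indexed by donor_id."""
    frame = pd.read_csv(path, sep="\t", index_col="donor_id")
    return frame


# -- composition ----------------------------------------------------------

def write_composition(table: CompositionTable, prefix: str | Path) -> None:
    """Write counts as <prefix>.mtx with .rows.tsv / .cols.tsv sidecars."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(table.counts.values))
    rows = table.counts.index.to_frame(index=False)
    rows.to_csv(prefix.with_suffix(".rows.tsv"), sep="\t", index=False)
    pd.DataFrame({"subcluster": table.counts.columns}).to_csv(
        prefix.with_suffix(".cols.tsv"), sep="\t", index=False
    )
    prefix.with_suffix(".class.txt").write_text(table.broad_class + "\n")


def read_composition(prefix: str | Path) -> CompositionTable:
    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx"))).toarray().astype(np.int64)
    rows = pd.read_csv(prefix.with_suffix(".rows.tsv"), sep="\t")
    cols = pd.read_csv(prefix.with_suffix(".cols.tsv"), sep="\t")
    broad = prefix.with_suffix(".class.txt").read_text().strip()
    counts = pd.DataFrame(
        mat,
        index=pd.MultiIndex.from_frame(rows[["donor_id", "region"]]),
        columns=cols["subcluster"].tolist(),
    )
    return CompositionTable(counts=counts, broad_class=broad)


# -- BED ------------------------------------------------------------------

def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected at least 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as err:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from err
            name = parts[3] if len(parts) > 3 and parts[3] != "." else ""
            try:
                out.append(GenomicInterval(parts[0], start, end, name=name))
            except ValueError as err:
                raise ParseError(f"{path}:{lineno}: {err}") from err
    return out


# -- JSON / YAML ----------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_yaml(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path: str | Path):
    with open(path) as fh:
        return yaml.safe_load(fh)
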