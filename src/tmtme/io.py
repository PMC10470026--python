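"""Reading and validating the pipeline's tabular inputs, writing its outputs.

Input conventions: TSV with a header row; expression oriented genes x
samples with the gene id in the first column (the common TCGA/CGGA export
shape, transposable via ``orientation``); expression values are
log2(TPM+1), hence non-negative; immune fractions lie in [0, 1] with rows
on the simplex; the clinical table has columns sample_id / time / event
(time in days, event 1 = death).  Gene and sample identifiers are matched
by exact, case-sensitive string equality.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .survival import SurvivalData, ValidationError

logger = logging.getLogger(__name__)

SIMPLEX_WARN_TOL = 1e-6


def read_matrix(path, orientation: str = "genes_by_samples",
                nonnegative: bool = False, unit_interval: bool = False,
                name: str = "matrix") -> pd.DataFrame:
    """Read a feature matrix as a samples x features DataFrame.

    ``orientation`` describes the file: "genes_by_samples" (features in
    rows, first column the feature id — transposed on read) or
    "samples_by_features" (sample id in the first column).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:  # pandas silently renames duplicate header fields
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"{name} {path}: duplicate header ids {dup[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "genes_by_samples":
        df = df.T
    elif orientation != "samples_by_features":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise ValidationError(f"{name} {path}: duplicate sample ids {dup[:5]}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].tolist()
        raise ValidationError(f"{name} {path}: duplicate feature ids {dup[:5]}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{name} {path}: non-numeric entries ({exc})") from None
    if df.isna().any().any():
        raise ValidationError(f"{name} {path}: missing values")
    if nonnegative and (df.to_numpy() < 0).any():
        r, c = np.argwhere(df.to_numpy() < 0)[0]
        raise ValidationError(
            f"{name} {path}: negative value at sample {df.index[r]!r}, "
            f"feature {df.columns[c]!r}; log2(TPM+1) input must be non-negative")
    if unit_interval:
        vals = df.to_numpy()
        if ((vals < 0) | (vals > 1)).any():
            r, c = np.argwhere((vals < 0) | (vals > 1))[0]
            raise ValidationError(
                f"{name} {path}: fraction outside [0, 1] at sample "
                f"{df.index[r]!r}, column {df.columns[c]!r}")
        dev = np.abs(vals.sum(axis=1) - 1.0)
        if (dev > SIMPLEX_WARN_TOL).any():
            logger.warning("%s %s: %d row(s) deviate from unit sum by up to %.2g",
                           name, path, int((dev > SIMPLEX_WARN_TOL).sum()), dev.max())
    return df


def read_expression(path, orientation: str = "genes_by_samples") -> pd.DataFrame:
    return read_matrix(path, orientation=orientation, nonnegative=True,
                       name="expression matrix")


def read_fractions(path, orientation: str = "samples_by_features") -> pd.DataFrame:
    return read_matrix(path, orientation=orientation, unit_interval=True,
                       name="fraction matrix")


def read_clinical(path) -> tuple[SurvivalData, pd.DataFrame]:
    """Read the clinical table; returns the outcome plus any extra covariates."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ValidationError(f"clinical table {path}: missing column {col!r}")
    df["sample_id"] = df["sample_id"].astype(str)
    ev = df["event"]
    if not ev.isin([0, 1]).all():
        bad = ev[~ev.isin([0, 1])].unique().tolist()
        raise ValidationError(
            f"clinical table {path}: column 'event' must be 0/1, found {bad[:5]}")
    surv = SurvivalData(df["sample_id"].to_numpy(), df["time"].to_numpy(),
                        df["event"].to_numpy())
    extra = df.drop(columns=["time", "event"]).set_index("sample_id")
    extra.index = extra.index.astype(str)
    return surv, extra


def read_gene_list(path) -> list[str]:
    """Candidate gene list: one identifier per line, '#' comments allowed."""
    genes = []
    for line in Path(path).read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            genes.append(token)
    if not genes:
        raise ValidationError(f"candidate gene list {path} is empty")
    if len(set(genes)) != len(genes):
        raise ValidationError(f"candidate gene list {path} has duplicates")
    return genes


def intersect_samples(expression: pd.DataFrame, fractions: pd.DataFrame,
                      survival: SurvivalData):
    """Restrict all three inputs to their common samples (order: clinical)."""
    ids = [set(expression.index), set(fractions.index), set(survival.sample_ids)]
    common = [s for s in survival.sample_ids if s in ids[0] and s in ids[1]]
    dropped = sorted(set().union(*ids) - set(common))
    if not common:
        raise ValidationError("no sample is shared by expression, fractions "
                              "and clinical inputs")
    if dropped:
        logger.warning("excluding %d sample(s) absent from some input: %s%s",
                       len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")
    return (expression.loc[common], fractions.loc[common],
            survival.reindex(common), dropped)


# ---------------------------------------------------------------------------
# deterministic output writers
# ---------------------------------------------------------------------------

def write_json(obj, path) -> None:
    """JSON with sorted keys and a trailing newline; byte-stable for a given obj."""
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True,
                                     allow_nan=False) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if np.isnan(f):
            return None
        return f if np.isfinite(f) else ("Infinity" if f > 0 else "-Infinity")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")
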