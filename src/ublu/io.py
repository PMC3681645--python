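"""Reading expression matrices and writing/reading run results.

Matrices are delimited text (TSV or CSV) with one header row and one
identifier column; the on-disk orientation defaults to genes in rows.
Results are written as TSV tables plus a JSON run summary; all floats use 17
significant digits so a save/load round trip is bit-exact.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, FactorModel
from .exceptions import ConstraintError, ParseError

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


def _read_table(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except Exception as exc:  # malformed file structure
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path} has no data columns")
    return df


def load_expression_matrix(path, genes_in: str = "rows") -> ExpressionMatrix:
    """Load a delimited expression matrix, oriented genes x samples.

    Parameters
    ----------
    path
        TSV (default) or CSV file with a header row and an identifier column.
    genes_in
        ``rows`` if genes are the file's rows (the default convention),
        ``columns`` if the file is transposed.

    Raises
    ------
    ParseError
        Non-numeric or missing cells (named by row/column identifier).
    ConstraintError
        Negative entries; the positivity interpretation of factors requires
        non-negative input (constraint_mode=none relaxes the fit, not the
        loader).
    """
    if genes_in not in ("rows", "columns"):
        raise ParseError(f"genes_in must be 'rows' or 'columns', got {genes_in!r}")
    path = Path(path)
    df = _read_table(path)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric cell {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} of {path}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"missing cell at row {df.index[i]!r}, column {df.columns[j]!r} "
            f"of {path}; missing values are not imputed"
        )
    if genes_in == "columns":
        numeric = numeric.T
    return ExpressionMatrix(
        values=numeric.to_numpy(dtype=np.float64),
        gene_ids=[str(g) for g in numeric.index],
        sample_ids=[str(s) for s in numeric.columns],
    )


def save_expression_matrix(Y: ExpressionMatrix, path) -> None:
    """Write an expression matrix as TSV, genes in rows."""
    df = pd.DataFrame(Y.values, index=Y.gene_ids, columns=Y.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def save_run(trace, estimates: FactorModel, out_dir, overwrite: bool = False) -> Path:
    """Write a run's estimates, traces, and summary to ``out_dir``.

    Files: ``factors.tsv`` (genes x R), ``scores.tsv`` (R x samples),
    ``re_trace.txt``, ``r_samples.txt``, and ``summary.json`` (sigma2_hat,
    MAP factor count, factor-count histogram, per-move acceptance counters,
    resolved configuration, fitted projection basis).

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out} exists and is not empty; pass overwrite=True to replace it"
        )
    out.mkdir(parents=True, exist_ok=True)

    R = estimates.R
    gene_ids = trace.gene_ids or [f"gene_{i + 1:05d}" for i in range(estimates.M.shape[0])]
    sample_ids = trace.sample_ids or [f"sample_{j + 1:04d}" for j in range(estimates.A.shape[1])]
    factor_ids = [f"factor_{r + 1}" for r in range(R)]

    mdf = pd.DataFrame(estimates.M, index=gene_ids, columns=factor_ids)
    mdf.index.name = "gene_id"
    mdf.to_csv(out / "factors.tsv", sep="\t", float_format=_FLOAT_FMT)

    adf = pd.DataFrame(estimates.A, index=factor_ids, columns=sample_ids)
    adf.index.name = "factor_id"
    adf.to_csv(out / "scores.tsv", sep="\t", float_format=_FLOAT_FMT)

    np.savetxt(out / "re_trace.txt", np.asarray(trace.re_trace), fmt=_FLOAT_FMT)
    np.savetxt(out / "r_samples.txt", np.asarray(trace.R_samples), fmt="%d")

    hist = trace.r_histogram()
    summary = {
        "r_hat": int(max(sorted(hist), key=lambda k: hist[k])) if hist else None,
        "sigma2_hat": float(estimates.sigma2),
        "r_histogram": {str(k): v for k, v in sorted(hist.items())},
        "acceptance": trace.acceptance,
        "config": trace.config.to_dict(),
        "basis": trace.basis.to_dict(),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    logger.info("wrote run results to %s", out)
    return out


def load_run(out_dir):
    """Re-load a saved run; returns (FactorModel, summary dict).

    Inverse of :func:`save_run` for the estimates: matrices round-trip
    bit-exactly.
    """
    out = Path(out_dir)
    mdf = pd.read_csv(out / "factors.tsv", sep="\t", index_col=0,
                      float_precision="round_trip")
    adf = pd.read_csv(out / "scores.tsv", sep="\t", index_col=0,
                      float_precision="round_trip")
    with open(out / "summary.json") as fh:
        summary = json.load(fh)
    model = FactorModel(
        M=mdf.to_numpy(dtype=np.float64),
        A=adf.to_numpy(dtype=np.float64),
        sigma2=summary["sigma2_hat"],
    )
    return model, summary


def r_sample_histogram(r_samples) -> dict[int, int]:
    """Histogram of factor-count samples (used for the run summary)."""
    values, counts = np.unique(np.asarray(r_samples, dtype=int), return_counts=True)
    return {int(v): int(c) for v, c in zip(values, counts)}
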