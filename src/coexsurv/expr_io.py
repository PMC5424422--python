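"""Reading, validation, probe collapsing and pre-filtering of expression data.

Expression matrices are plain pandas DataFrames with genes in rows (unique
symbols in the index) and samples in columns, holding log2-scale continuous
values.  Clinical tables are DataFrames with one row per sample.  All readers
accept tab-separated UTF-8 text; lines starting with ``#`` are treated as
comments so that pipeline outputs (which carry a config header) can be
re-ingested.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns a clinical table must provide.
CLINICAL_REQUIRED = ("sample_id", "rfs_months", "event")
#: Optional clinical columns that are carried through when present.
CLINICAL_OPTIONAL = ("stage", "msi", "cimp", "braf", "kras", "batch")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path, dialect: str = "genes-in-rows") -> pd.DataFrame:
    """Read an expression matrix from TSV (header = sample ids, first column
    = gene/probe ids) and validate it.

    Raises ``ValueError`` on duplicate sample or gene identifiers and on any
    non-numeric or missing cell, naming the offending row/column.
    """
    if dialect != "genes-in-rows":
        raise ValueError(f"unsupported dialect: {dialect!r}")
    # pandas renames duplicate header fields; check the raw header first
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")[1:]
                break
        else:
            raise ValueError(f"empty expression file: {path}")
    seen: set = set()
    for name in header:
        if name in seen:
            raise ValueError(f"duplicate sample identifier in {path}: "
                             f"{name!r}")
        seen.add(name)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene identifier in {path}: {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate sample identifier in {path}: {dup!r}")
    if any(c.startswith("Unnamed:") for c in df.columns):
        raise ValueError(f"missing sample identifier in header of {path}")
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(values.to_numpy(dtype=float, na_value=np.nan))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric or missing value at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r} in {path}"
        )
    out = values.astype(float)
    logger.info("read expression matrix %s: %d genes x %d samples",
                path, *out.shape)
    return out


def write_expression(expr: pd.DataFrame, path, header_lines=()) -> None:
    """Write an expression matrix as TSV; ``header_lines`` are emitted as
    leading ``#`` comments."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        expr.to_csv(fh, sep="\t", index_label="gene_id", lineterminator="\n")


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check the ExpressionMatrix invariants on an in-memory frame."""
    if expr.index.duplicated().any():
        raise ValueError("duplicate gene identifiers")
    if expr.columns.duplicated().any():
        raise ValueError("duplicate sample identifiers")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    return expr


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

def read_clinical(path) -> pd.DataFrame:
    """Read and validate a clinical annotation table (TSV, one row per
    sample; columns ``sample_id``, ``rfs_months``, ``event`` required)."""
    clin = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    return validate_clinical(clin)


def validate_clinical(clin: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLINICAL_REQUIRED if c not in clin.columns]
    if missing:
        raise ValueError(f"clinical table lacks required columns: {missing}")
    if clin["sample_id"].duplicated().any():
        dup = clin.loc[clin["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in clinical table: {dup!r}")
    t = pd.to_numeric(clin["rfs_months"], errors="coerce")
    if t.isna().any() or (t < 0).any():
        raise ValueError("rfs_months must be non-negative numbers")
    ev = pd.to_numeric(clin["event"], errors="coerce")
    if not ev.isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    if ((ev == 1) & (t <= 0)).any():
        raise ValueError("event=1 requires rfs_months > 0")
    out = clin.copy()
    out["rfs_months"] = t.astype(float)
    out["event"] = ev.astype(int)
    return out


def censor_rfs(clin: pd.DataFrame, cutoff_months: float = 60.0) -> pd.DataFrame:
    """Administratively censor recurrence-free survival at ``cutoff_months``
    (5 years by default): times beyond the cutoff are set to the cutoff and
    their events cleared.  Idempotent."""
    if cutoff_months <= 0:
        raise ValueError("cutoff_months must be positive")
    clin = validate_clinical(clin)
    out = clin.copy()
    beyond = out["rfs_months"] > cutoff_months
    out.loc[beyond, "rfs_months"] = float(cutoff_months)
    out.loc[beyond, "event"] = 0
    logger.info("censored %d of %d records at %.0f months",
                int(beyond.sum()), len(out), cutoff_months)
    return out


# ---------------------------------------------------------------------------
# probe tables and collapsing
# ---------------------------------------------------------------------------

def read_probe_table(path) -> pd.DataFrame:
    """Read a probe→gene mapping table (columns ``probe_id``,
    ``gene_symbol``; empty symbol = unannotated probe)."""
    tab = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                      keep_default_na=False)
    if "probe_id" not in tab.columns or "gene_symbol" not in tab.columns:
        raise ValueError("probe table needs columns probe_id, gene_symbol")
    if tab["probe_id"].duplicated().any():
        dup = tab.loc[tab["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe_id: {dup!r}")
    return tab


def collapse_probes(expr: pd.DataFrame, probe_map: pd.DataFrame,
                    method: str = "maxmean") -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level.

    Probes with an empty gene symbol are dropped (unannotated).  For genes
    measured by several probes the probe with the largest mean expression
    across samples is retained (MaxMean rule; ties broken by lexicographic
    probe id).  Every probe in ``expr`` must appear in ``probe_map``.
    """
    if method != "maxmean":
        raise ValueError(f"unknown collapse method: {method!r}")
    mapping = probe_map.set_index("probe_id")["gene_symbol"]
    missing = expr.index.difference(mapping.index)
    if len(missing):
        raise ValueError(f"probe absent from mapping table: {missing[0]!r}")
    symbols = mapping.reindex(expr.index)
    keep = symbols.notna() & (symbols.str.strip() != "")
    expr = expr.loc[keep]
    symbols = symbols.loc[keep]
    means = expr.mean(axis=1)
    choice = (
        pd.DataFrame({"gene": symbols.values, "mean": means.values,
                      "probe": expr.index})
        .sort_values(["gene", "mean", "probe"],
                     ascending=[True, False, True], kind="mergesort")
        .drop_duplicates("gene", keep="first")
    )
    out = expr.loc[choice["probe"]]
    out.index = pd.Index(choice["gene"].values, name="gene_id")
    logger.info("collapsed %d probes to %d genes", int(keep.sum()), len(out))
    return out


# ---------------------------------------------------------------------------
# pre-filters
# ---------------------------------------------------------------------------

def filter_by_variance(expr: pd.DataFrame, n_top: int = 5000) -> pd.DataFrame:
    """Keep the ``n_top`` genes with the largest sample standard deviation
    (ddof=1).  Ties broken by lexicographic gene symbol; input gene and
    sample order preserved for the survivors."""
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > expr.shape[0]:
        raise ValueError(f"n_top={n_top} exceeds gene count {expr.shape[0]}")
    sd = expr.std(axis=1, ddof=1)
    ranked = sd.to_frame("sd").assign(gene=sd.index).sort_values(
        ["sd", "gene"], ascending=[False, True], kind="mergesort")
    selected = set(ranked.index[:n_top])
    out = expr.loc[[g for g in expr.index if g in selected]]
    logger.info("variance filter: kept %d of %d genes (min SD %.4g)",
                len(out), len(expr), float(ranked["sd"].iloc[n_top - 1]))
    return out


def filter_by_connectivity(expr: pd.DataFrame, beta: float,
                           n_top: int = 3600) -> pd.DataFrame:
    """Keep the ``n_top`` most connected genes, ranking by whole-network
    connectivity k.total on the soft-thresholded adjacency at ``beta``.
    Ties broken by lexicographic gene symbol."""
    from .netbuild import connectivity, pearson_adjacency

    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > expr.shape[0]:
        raise ValueError(f"n_top={n_top} exceeds gene count {expr.shape[0]}")
    adj = pearson_adjacency(expr, beta)
    k = connectivity(adj)["k_total"]
    ranked = k.to_frame("k").assign(gene=k.index).sort_values(
        ["k", "gene"], ascending=[False, True], kind="mergesort")
    selected = set(ranked.index[:n_top])
    out = expr.loc[[g for g in expr.index if g in selected]]
    logger.info("connectivity filter (beta=%g): kept %d of %d genes",
                beta, len(out), len(expr))
    return out
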