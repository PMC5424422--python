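"""Survival association of modules and genes, hub-gene selection, subtypes.

Module eigengenes are robustly scaled (2.5%/50%/97.5% quantiles mapped to
−1/0/+1) and treated as continuous covariates in univariate Cox
proportional-hazards models of recurrence-free survival; single genes are
fitted on their raw expression.  Gene significance GS = −log10(Cox p).
Hub genes are the module members with k.in among the module's top 10 that
also reach GS > 2.  Molecular subtypes 1–5 are a pure function of the
MSI/CIMP/BRAF/KRAS marker combination.

The Cox fit is a single-covariate Newton–Raphson maximiser of the partial
likelihood with Efron (default) or Breslow handling of tied event times;
HR = exp(b), 95% CI = exp(b ± 1.96·SE), p = two-sided Wald.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Raised when the Cox partial likelihood cannot be maximised."""


# ---------------------------------------------------------------------------
# eigengene scaling
# ---------------------------------------------------------------------------

def scale_eigengene(me) -> np.ndarray | pd.Series:
    """Piecewise-linear robust scaling of an eigengene.

    The 2.5%, 50% and 97.5% quantiles (linear interpolation) map to −1, 0
    and +1; values between them interpolate linearly on their segment and
    values outside extrapolate on the segment's slope.  Monotone; the
    median maps exactly to 0.
    """
    x = np.asarray(me, dtype=float)
    q_lo, q_mid, q_hi = np.quantile(x, [0.025, 0.5, 0.975])
    if q_lo == q_mid or q_mid == q_hi:
        raise ValueError("degenerate eigengene: scaling quantiles coincide")
    out = np.where(x <= q_mid,
                   (x - q_mid) / (q_mid - q_lo),
                   (x - q_mid) / (q_hi - q_mid))
    if isinstance(me, pd.Series):
        return pd.Series(out, index=me.index, name=me.name)
    return out


def dichotomise_eigengene(me) -> np.ndarray | pd.Series:
    """Median split of an eigengene (0 = below/at median, 1 = above)."""
    x = np.asarray(me, dtype=float)
    out = (x > np.median(x)).astype(float)
    if isinstance(me, pd.Series):
        return pd.Series(out, index=me.index, name=me.name)
    return out


# ---------------------------------------------------------------------------
# Cox proportional hazards (single covariate)
# ---------------------------------------------------------------------------

@dataclass
class AssociationRecord:
    """Univariate Cox association of one target in one stratum."""

    target: str
    stratum: str
    n: int
    n_events: int
    coef: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    gs: float
    fdr: float = float("nan")


def _cox_groups(time: np.ndarray, event: np.ndarray):
    """Risk-set group structure: indices grouped by distinct time, in
    decreasing time order, with the event subset of each group."""
    order = np.argsort(-time, kind="mergesort")
    groups = []
    i = 0
    while i < order.size:
        j = i
        while j < order.size and time[order[j]] == time[order[i]]:
            j += 1
        idx = order[i:j]
        groups.append((idx, idx[event[idx] == 1]))
        i = j
    return groups


def _cox_loglik(beta: float, x, groups, efron: bool):
    """Partial log-likelihood, score and observed information at beta."""
    r = np.exp(beta * x)
    rx = r * x
    rxx = rx * x
    s0 = s1 = s2 = 0.0
    ll = score = info = 0.0
    for idx, ev in groups:
        s0 += r[idx].sum()
        s1 += rx[idx].sum()
        s2 += rxx[idx].sum()
        d = ev.size
        if d == 0:
            continue
        ll += beta * x[ev].sum()
        score += x[ev].sum()
        s0d, s1d, s2d = r[ev].sum(), rx[ev].sum(), rxx[ev].sum()
        for j in range(d):
            phi = j / d if efron else 0.0
            z0 = s0 - phi * s0d
            z1 = s1 - phi * s1d
            z2 = s2 - phi * s2d
            m = z1 / z0
            ll -= np.log(z0)
            score -= m
            info += z2 / z0 - m * m
    return ll, score, info


def cox_fit(covariate, time, event, *, ties: str = "efron",
            tol: float = 1e-9, max_iter: int = 100,
            target: str = "", stratum: str = "all") -> AssociationRecord:
    """Univariate Cox proportional-hazards fit by Newton–Raphson.

    Requires at least one event and a finite, non-constant covariate.
    Raises ``ConvergenceError`` on non-convergence (e.g. monotone
    separation of events along the covariate).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie handling: {ties!r}")
    x = np.asarray(covariate, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if not (x.size == t.size == e.size):
        raise ValueError("covariate, time and event lengths differ")
    if not np.isfinite(x).all():
        raise ValueError("covariate contains non-finite values")
    if e.sum() < 1:
        raise ValueError("need at least one event")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")

    center = x.mean()
    xc = x - center                    # translation-invariant; HR unchanged
    groups = _cox_groups(t, e)
    efron = ties == "efron"

    beta = 0.0
    ll, score, info = _cox_loglik(beta, xc, groups, efron)
    for _ in range(max_iter):
        if info <= 0:
            raise ConvergenceError("non-positive information; degenerate fit")
        step = score / info
        # step-halving safeguard against overshooting
        for _ in range(30):
            cand = beta + step
            ll_new, score_new, info_new = _cox_loglik(cand, xc, groups, efron)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            raise ConvergenceError("step halving failed; likely separation")
        converged = abs(step) < tol
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if abs(beta) > 50:
            raise ConvergenceError(
                "coefficient diverging (|b| > 50); monotone separation of "
                "events along the covariate")
        if converged:
            break
    else:
        raise ConvergenceError(f"no convergence in {max_iter} iterations "
                               f"(last step {step:.3g})")

    se = float(1.0 / np.sqrt(info))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return AssociationRecord(
        target=target, stratum=stratum, n=int(x.size), n_events=int(e.sum()),
        coef=float(beta), se=se, hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        p=p, gs=float(-np.log10(p)) if p > 0 else np.inf)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def _records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    if len(df):
        df["fdr"] = benjamini_hochberg(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# module / gene association
# ---------------------------------------------------------------------------

def _stratum_samples(sample_ids: pd.Index, stratum: str,
                     subtypes: pd.Series | None) -> pd.Index:
    if stratum == "all":
        return sample_ids
    if subtypes is None:
        raise ValueError(f"stratum {stratum!r} requires subtype labels")
    keep = subtypes.reindex(sample_ids) == stratum
    return sample_ids[keep.to_numpy(dtype=bool)]


def _check_events(time, event, stratum):
    n_ev = int(np.asarray(event).sum())
    if n_ev < 10:
        warnings.warn(f"stratum {stratum!r} has only {n_ev} events; "
                      "estimates will be unstable")


def associate_modules(scaled_mes: pd.DataFrame, clin: pd.DataFrame,
                      stratum: str = "all",
                      subtypes: pd.Series | None = None,
                      ties: str = "efron") -> pd.DataFrame:
    """Cox association of every module's (scaled) eigengene with survival
    in one stratum, with BH FDR across the module family.

    ``scaled_mes``: modules × samples covariate matrix (scaled or
    dichotomised eigengenes); ``clin``: clinical table with ``sample_id``,
    ``rfs_months`` and ``event``.
    """
    clin_idx = clin.set_index("sample_id")
    samples = _stratum_samples(
        scaled_mes.columns.intersection(clin_idx.index), stratum, subtypes)
    sub = clin_idx.loc[samples]
    _check_events(sub["rfs_months"], sub["event"], stratum)
    records = []
    for mod in scaled_mes.index:
        records.append(cox_fit(
            scaled_mes.loc[mod, samples], sub["rfs_months"], sub["event"],
            ties=ties, target=str(mod), stratum=stratum))
    return _records_to_frame(records)


def associate_genes(expr: pd.DataFrame, clin: pd.DataFrame,
                    genes=None, stratum: str = "all",
                    subtypes: pd.Series | None = None,
                    ties: str = "efron") -> pd.DataFrame:
    """Per-gene Cox association with survival (expression as a continuous
    covariate); GS = −log10(p); BH FDR within the queried gene family
    (e.g. one module's members)."""
    if genes is None:
        genes = expr.index
    clin_idx = clin.set_index("sample_id")
    samples = _stratum_samples(
        expr.columns.intersection(clin_idx.index), stratum, subtypes)
    sub = clin_idx.loc[samples]
    _check_events(sub["rfs_months"], sub["event"], stratum)
    records = []
    for gene in genes:
        records.append(cox_fit(
            expr.loc[gene, samples], sub["rfs_months"], sub["event"],
            ties=ties, target=str(gene), stratum=stratum))
    return _records_to_frame(records)


def module_trait_correlation(me, trait) -> tuple[float, float]:
    """Pearson correlation of an eigengene with a numerically coded trait
    (e.g. tumour stage II→2, III→3) and its two-sided t-test p-value."""
    x = np.asarray(me, dtype=float)
    y = np.asarray(trait, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(y) == 0:
        raise ValueError("constant trait vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def code_stage(stage: pd.Series) -> pd.Series:
    """Code tumour stage II→2, III→3 for correlation analyses."""
    mapping = {"II": 2.0, "III": 3.0, "2": 2.0, "3": 3.0}
    coded = stage.astype(str).map(mapping)
    if coded.isna().any():
        bad = stage[coded.isna()].iloc[0]
        raise ValueError(f"unrecognised stage value: {bad!r}")
    return coded


# ---------------------------------------------------------------------------
# molecular subtypes
# ---------------------------------------------------------------------------

UNCLASSIFIED = "unclassified"

#: (msi, cimp, braf, kras) → subtype label.
SUBTYPE_RULES = {
    ("high", "positive", "mutant", "wildtype"): "type1",
    ("low", "positive", "mutant", "wildtype"): "type2",
    ("low", "negative", "wildtype", "mutant"): "type3",
    ("low", "negative", "wildtype", "wildtype"): "type4",
    ("high", "negative", "wildtype", "wildtype"): "type5",
}

_MARKER_LEVELS = {
    "msi": ("high", "low"),
    "cimp": ("positive", "negative"),
    "braf": ("mutant", "wildtype"),
    "kras": ("mutant", "wildtype"),
}


def assign_subtype(msi, cimp, braf, kras) -> str:
    """Molecular subtype from MSI/CIMP status and BRAF/KRAS mutation;
    any missing or unknown marker value → ``"unclassified"``.  Total
    function (never raises)."""
    key = tuple(str(v).strip().lower() for v in (msi, cimp, braf, kras))
    for marker, value in zip(_MARKER_LEVELS, key):
        if value not in _MARKER_LEVELS[marker]:
            return UNCLASSIFIED
    return SUBTYPE_RULES.get(key, UNCLASSIFIED)


def assign_subtypes(clin: pd.DataFrame) -> pd.Series:
    """Vectorised subtype assignment over a clinical table; returns a
    Series indexed by sample_id."""
    labels = [assign_subtype(row.get("msi"), row.get("cimp"),
                             row.get("braf"), row.get("kras"))
              for _, row in clin.iterrows()]
    return pd.Series(labels, index=pd.Index(clin["sample_id"],
                                            name="sample_id"),
                     name="subtype")


# ---------------------------------------------------------------------------
# hub genes
# ---------------------------------------------------------------------------

def select_hub_genes(partition: pd.Series, conn: pd.DataFrame,
                     gene_assoc: pd.DataFrame, module: str) -> pd.DataFrame:
    """Hub-gene report for one module.

    Members are ranked by within-module connectivity k.in (descending,
    ties broken by lexicographic gene symbol); a member is a hub iff its
    k.in rank is ≤ 10 and its survival gene significance GS exceeds 2.
    """
    members = partition.index[partition == module]
    if len(members) == 0:
        raise ValueError(f"module {module!r} has no members")
    gs = gene_assoc.set_index("target")["gs"].reindex(members.astype(str))
    k_in = conn.loc[members, "k_in"]
    rep = pd.DataFrame({
        "module": module,
        "gene_id": members,
        "k_in": k_in.to_numpy(dtype=float),
        "gs": gs.to_numpy(dtype=float),
    }).sort_values(["k_in", "gene_id"], ascending=[False, True],
                   kind="mergesort")
    rep["k_in_rank"] = np.arange(1, len(rep) + 1)
    rep["is_hub"] = (rep["k_in_rank"] <= 10) & (rep["gs"] > 2)
    return rep.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Kaplan-Meier curves
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival curve for one group."""

    label: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int


def km_curves(values, time, event, n_groups: int = 3,
              labels=("low", "mid", "high")) -> tuple[list[KMCurve], float]:
    """Kaplan-Meier curves for samples grouped by quantile of a covariate
    (tertiles by default), plus the log-rank p-value across groups.

    Raises on empty groups (e.g. from heavily tied covariates).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    x = np.asarray(values, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    qs = np.quantile(x, np.linspace(0, 1, n_groups + 1)[1:-1])
    group = np.searchsorted(qs, x, side="left")
    curves = []
    for g in range(n_groups):
        mask = group == g
        if not mask.any():
            raise ValueError(f"empty group {labels[g]!r} in KM grouping")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask])
        timeline = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
        curves.append(KMCurve(labels[g], timeline, surv, at_risk,
                              int(mask.sum()), int(e[mask].sum())))
    if e.sum() > 0 and len(np.unique(group)) > 1:
        lr = multivariate_logrank_test(t, group, e)
        logrank_p = float(lr.p_value)
    else:
        logrank_p = float("nan")
    return curves, logrank_p
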