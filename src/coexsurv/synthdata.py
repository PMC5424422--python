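"""Synthetic expression, survival and subtype data with known ground truth.

The expression generator plants gene modules under a latent-factor (spiked
covariance) model: module m has a standard-normal factor f_m per sample and
each member gene g is x_g = u_g·f_m + ε with loading u_g ∈ (0, 1] and
Gaussian noise.  Background genes are pure noise.  The implied within-module
correlation is u_g·u_h / sqrt((u_g²+σ²)(u_h²+σ²)), giving eigengene recovery
an analytic ground truth.

Survival times follow an exponential proportional-hazards model whose
log-hazard is a linear combination of the planted modules' *scaled
eigengenes* — the eigengenes are recomputed from the generated matrix with
the pipeline's own eigengene and scaling code, so the whole analysis loop is
inside the tested path.  Independent uniform censoring is tuned by bisection
to hit a requested censoring fraction, and administrative censoring at the
recurrence-free-survival cutoff (60 months) is applied on top.

Subtype labels are drawn with marker columns (MSI/CIMP/BRAF/KRAS) consistent
with the subtype rule table, so label assignment inverts the generation
exactly; the default composition mirrors a 461-patient stage II/III colon
cancer cohort (26/6/108/151/8 classified, remainder missing markers).

All randomness flows from one explicit integer seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .moduledetect import GREY, module_eigengene
from .survassoc import SUBTYPE_RULES, UNCLASSIFIED, scale_eigengene

logger = logging.getLogger(__name__)

BACKGROUND = "background"

#: Default planted-module sizes: 11 modules spanning 35-866 genes, the size
#: envelope of a real colon-cancer co-expression analysis at 3600 genes.
DEFAULT_MODULE_SIZES = (866, 369, 179, 170, 108, 82, 52, 48, 44, 41, 35)

#: Default subtype composition of a 461-sample cohort
#: (type1..type5 counts; the remainder has missing markers).
DEFAULT_SUBTYPE_COUNTS = (26, 6, 108, 151, 8)

_MARKERS = ("msi", "cimp", "braf", "kras")
_RULE_BY_TYPE = {label: key for key, label in SUBTYPE_RULES.items()}


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    partition: pd.Series            # gene -> module label or "background"
    loadings: pd.Series             # per-gene factor loading (0 for background)
    factors: pd.DataFrame           # modules x samples latent factors
    module_log_hr: dict             # module label -> log-HR on scaled ME
    censor_fraction: float | None
    seed: int
    batch: pd.Series | None = None
    subtypes: pd.Series | None = None

    def to_json(self, path) -> None:
        payload = {
            "partition": self.partition.to_dict(),
            "loadings": self.loadings.to_dict(),
            "factors": {m: list(map(float, self.factors.loc[m]))
                        for m in self.factors.index},
            "factor_samples": list(self.factors.columns),
            "module_log_hr": self.module_log_hr,
            "censor_fraction": self.censor_fraction,
            "seed": self.seed,
            "batch": None if self.batch is None else self.batch.to_dict(),
            "subtypes": (None if self.subtypes is None
                         else self.subtypes.to_dict()),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        factors = pd.DataFrame(payload["factors"],
                               index=payload["factor_samples"]).T
        return cls(
            partition=pd.Series(payload["partition"], name="module"),
            loadings=pd.Series(payload["loadings"], name="loading"),
            factors=factors,
            module_log_hr=payload["module_log_hr"],
            censor_fraction=payload["censor_fraction"],
            seed=payload["seed"],
            batch=(None if payload["batch"] is None
                   else pd.Series(payload["batch"], name="batch")),
            subtypes=(None if payload["subtypes"] is None
                      else pd.Series(payload["subtypes"], name="subtype")),
        )

    def grey_partition(self) -> pd.Series:
        """Planted partition with background genes relabelled grey, for
        direct use with the module-eigengene code."""
        return self.partition.replace(BACKGROUND, GREY)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(n_genes: int = 3600, n_samples: int = 461,
                        module_sizes=DEFAULT_MODULE_SIZES,
                        loading_range: tuple[float, float] = (0.3, 0.9),
                        noise_sd: float = 1.0,
                        batch_shift: float | None = None,
                        n_batches: int = 2,
                        module_log_hr: dict | None = None,
                        seed: int = 0) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a gene-level log-expression matrix with planted modules.

    Returns the genes × samples matrix and the ground truth.  Module
    labels are ``m1``, ``m2``, ... in the order of ``module_sizes``;
    remaining genes are background noise.  ``batch_shift``, when given,
    adds a per-batch constant offset to every gene (batch labels recorded
    in the truth).  Deterministic under ``seed``.
    """
    module_sizes = list(module_sizes)
    if sum(module_sizes) > n_genes:
        raise ValueError("module sizes exceed the gene count")
    lo, hi = loading_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError("loading range must lie within (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    sample_ids = [f"S{j + 1:04d}" for j in range(n_samples)]
    labels = np.array([BACKGROUND] * n_genes, dtype=object)
    loadings = np.zeros(n_genes)
    x = rng.normal(0.0, noise_sd if noise_sd > 0 else 1e-12,
                   size=(n_genes, n_samples))
    factors = {}
    start = 0
    for mi, size in enumerate(module_sizes, start=1):
        mod = f"m{mi}"
        f = rng.standard_normal(n_samples)
        u = rng.uniform(lo, hi, size=size)
        rows = slice(start, start + size)
        x[rows] += u[:, None] * f[None, :]
        labels[rows] = mod
        loadings[rows] = u
        factors[mod] = f
        start += size
    batch = None
    if batch_shift is not None:
        assignment = rng.integers(0, n_batches, size=n_samples)
        offsets = (np.arange(n_batches) - (n_batches - 1) / 2) * batch_shift
        x += offsets[assignment][None, :]
        batch = pd.Series([f"batch{b + 1}" for b in assignment],
                          index=sample_ids, name="batch")
    expr = pd.DataFrame(x, index=pd.Index(gene_ids, name="gene_id"),
                        columns=sample_ids)
    truth = SyntheticTruth(
        partition=pd.Series(labels, index=expr.index, name="module"),
        loadings=pd.Series(loadings, index=expr.index, name="loading"),
        factors=pd.DataFrame(factors, index=sample_ids).T,
        module_log_hr=dict(module_log_hr or {}),
        censor_fraction=None, seed=int(seed), batch=batch)
    logger.info("simulated %d genes x %d samples, %d modules",
                n_genes, n_samples, len(module_sizes))
    return expr, truth


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def _tune_uniform_censoring(t_event: np.ndarray, u: np.ndarray,
                            cutoff: float, target: float) -> float:
    """Bisection on the uniform-censoring horizon so the realised censored
    fraction (uniform + administrative) matches ``target``."""

    def censored_fraction(c_max):
        c = u * c_max
        event = (t_event <= c) & (t_event <= cutoff)
        return 1.0 - event.mean()

    lo_c, hi_c = 1e-3, 1e7
    if censored_fraction(hi_c) > target:
        logger.warning("administrative censoring alone exceeds the target "
                       "censoring fraction %.2f", target)
        return hi_c
    if censored_fraction(lo_c) < target:
        return lo_c
    for _ in range(200):
        mid = np.sqrt(lo_c * hi_c)
        if censored_fraction(mid) > target:
            lo_c = mid
        else:
            hi_c = mid
    return hi_c


def generate_survival(expr: pd.DataFrame, truth: SyntheticTruth,
                      module_log_hr: dict | None = None,
                      baseline_rate: float = 0.03,
                      censor_fraction: float = 0.3,
                      cutoff: float = 60.0,
                      stage_probs: tuple[float, float] = (0.5, 0.5),
                      seed: int = 0) -> pd.DataFrame:
    """Simulate a clinical table with eigengene-driven survival.

    The hazard of sample i is λ·exp(Σ_m β_m·sME_m,i) where sME is the
    robustly scaled eigengene of planted module m recomputed from ``expr``
    with the pipeline's own code.  ``module_log_hr`` (default: the truth's)
    maps module labels to β.  Uniform censoring is tuned to the requested
    ``censor_fraction``; times are administratively censored at ``cutoff``.
    """
    if censor_fraction >= 1.0:
        raise ValueError("censor_fraction must be < 1 (degenerate: no "
                         "events would remain)")
    if censor_fraction < 0:
        raise ValueError("censor_fraction must be non-negative")
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    betas = dict(truth.module_log_hr)
    if module_log_hr is not None:
        betas.update(module_log_hr)
    rng = np.random.default_rng(seed)
    n = expr.shape[1]
    eta = np.zeros(n)
    active = {m: b for m, b in betas.items() if b != 0.0}
    if active:
        part = truth.grey_partition()
        keep = part.isin(list(active)) | (part == GREY)
        sub = part[keep].copy()
        sub[~sub.isin(list(active))] = GREY
        eig = module_eigengene(expr.loc[sub.index], sub)
        for mod, beta in active.items():
            eta += beta * np.asarray(
                scale_eigengene(eig.eigengenes.loc[mod]), dtype=float)
    hazard = baseline_rate * np.exp(eta)
    t_event = rng.exponential(1.0 / hazard)
    u = rng.uniform(size=n)
    c_max = _tune_uniform_censoring(t_event, u, cutoff, censor_fraction)
    c = u * c_max
    time = np.minimum(np.minimum(t_event, c), cutoff)
    event = ((t_event <= c) & (t_event <= cutoff)).astype(int)
    stage = rng.choice(["II", "III"], size=n, p=stage_probs)
    clin = pd.DataFrame({
        "sample_id": list(expr.columns),
        "rfs_months": time,
        "event": event,
        "stage": stage,
    })
    truth.censor_fraction = float(1.0 - event.mean())
    truth.module_log_hr = betas
    if truth.batch is not None:
        clin["batch"] = truth.batch.reindex(expr.columns).to_numpy()
    logger.info("simulated survival: %d/%d events (censoring %.1f%%)",
                int(event.sum()), n, 100 * (1 - event.mean()))
    return clin


# ---------------------------------------------------------------------------
# subtypes
# ---------------------------------------------------------------------------

def generate_subtypes(sample_ids, counts=None, proportions=None,
                      seed: int = 0) -> pd.DataFrame:
    """Draw subtype labels with marker columns consistent with the rule
    table (so assignment inverts generation exactly).

    Either exact ``counts`` (type1..type5) or ``proportions`` may be given;
    the default is the 26/6/108/151/8-of-461 cohort composition, scaled to
    the number of samples.  Unclassified samples get missing markers.
    Returns a DataFrame with columns sample_id, msi, cimp, braf, kras,
    subtype.
    """
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    if counts is not None and proportions is not None:
        raise ValueError("give counts or proportions, not both")
    if counts is None:
        if proportions is None:
            proportions = tuple(c / 461 for c in DEFAULT_SUBTYPE_COUNTS)
        proportions = [float(p) for p in proportions]
        if any(p < 0 for p in proportions):
            raise ValueError("proportions must be non-negative")
        if sum(proportions) > 1 + 1e-9:
            raise ValueError("proportions must sum to at most 1")
        counts = [int(round(p * n)) for p in proportions]
    counts = [int(c) for c in counts]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if sum(counts) > n:
        raise ValueError("subtype counts exceed the sample count")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = np.array([UNCLASSIFIED] * n, dtype=object)
    markers = {m: np.array(["missing"] * n, dtype=object) for m in _MARKERS}
    pos = 0
    for ti, c in enumerate(counts, start=1):
        label = f"type{ti}"
        rule = _RULE_BY_TYPE[label]
        idx = order[pos:pos + c]
        labels[idx] = label
        for marker, value in zip(_MARKERS, rule):
            markers[marker][idx] = value
        pos += c
    return pd.DataFrame({"sample_id": sample_ids, **markers,
                         "subtype": labels})


# ---------------------------------------------------------------------------
# bundled study simulation
# ---------------------------------------------------------------------------

def simulate_study(n_genes: int = 3600, n_samples: int = 461,
                   module_sizes=DEFAULT_MODULE_SIZES,
                   loading_range=(0.3, 0.9), noise_sd: float = 1.0,
                   module_log_hr: dict | None = None,
                   baseline_rate: float = 0.03,
                   censor_fraction: float = 0.3,
                   subtype_counts=None,
                   batch_shift: float | None = None,
                   seed: int = 0):
    """One-call cohort simulation: expression + clinical table (survival,
    stage, subtype markers) + ground truth."""
    rng = np.random.default_rng(seed)
    s_expr, s_surv, s_sub = rng.integers(0, 2 ** 31 - 1, size=3)
    expr, truth = generate_expression(
        n_genes=n_genes, n_samples=n_samples, module_sizes=module_sizes,
        loading_range=loading_range, noise_sd=noise_sd,
        batch_shift=batch_shift, module_log_hr=module_log_hr,
        seed=int(s_expr))
    clin = generate_survival(expr, truth, baseline_rate=baseline_rate,
                             censor_fraction=censor_fraction,
                             seed=int(s_surv))
    subs = generate_subtypes(expr.columns, counts=subtype_counts,
                             seed=int(s_sub))
    clin = clin.merge(subs.drop(columns="subtype"), on="sample_id")
    truth.subtypes = subs.set_index("sample_id")["subtype"]
    return expr, clin, truth
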