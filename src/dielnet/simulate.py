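"""Synthetic diel expression data with full ground truth.

Emulates the study design the pipeline targets: 12 timepoints sampled every
4 h over 44 h under a light:dark cycle, 4 technical replicates per
timepoint, cosine-shaped rhythmic genes whose peak phases follow a bimodal
(mid-day / mid-night) circular distribution, a lognormal-like spread of
peak-to-trough fold changes around a median of ~2, a raw-fluorescence
background floor, phase-coherent co-expression modules, and module-aligned
functional annotations.

Intensities are generated on the log2 scale and exponentiated, so the
background filter operates on raw fluorescence exactly as downstream
preprocessing expects.  All randomness flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix, sample_label
from .predict_function import AnnotationMap

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_expression",
    "generate_annotations",
    "generate_reference_rhythmic_set",
]

DEFAULT_TIMEPOINTS = tuple(float(h) for h in range(0, 48, 4))  # 0,4,...,44


@dataclass
class SimConfig:
    """Generator parameters (defaults mirror the emulated study design).

    ``frac_near_rhythmic`` plants additional low-amplitude ("sub-threshold")
    rhythmic genes inside co-expression modules; they are flagged separately
    in the ground truth and are off by default.
    """

    n_genes: int = 2000
    frac_rhythmic: float = 0.08
    n_modules: int = 4
    timepoints_h: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 4
    period_h: float = 24.0
    phase_modes_zt: tuple[float, float] = (6.0, 18.0)
    module_phase_spacing_h: float = 3.5  # centre spacing within a mode
    module_phase_window_h: float = 4.0  # members within +/- window/2 of centre
    fold_change_median: float = 2.06
    fold_change_spread: float = 0.5  # sd of log2 multiplicative deviation
    min_fold_change: float = 1.05
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.5
    noise_sd_log2: float = 0.15
    background_floor: float = 136.5
    frac_below_background: float = 0.05
    frac_near_rhythmic: float = 0.0
    near_fold_change: float = 1.10
    module_wiggle_rel: float = 0.5
    near_wiggle_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        t = np.asarray(self.timepoints_h, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("timepoints_h must be strictly increasing")
        for name in ("frac_rhythmic", "frac_below_background", "frac_near_rhythmic"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fold_change_median <= 1:
            raise ValueError("fold_change_median must exceed 1")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if 0 < round(self.frac_rhythmic * self.n_genes) < self.n_modules:
            raise ValueError("fewer rhythmic genes than modules")
        vals = [
            self.period_h,
            self.fold_change_spread,
            self.baseline_log2_mean,
            self.baseline_log2_sd,
            self.noise_sd_log2,
            self.background_floor,
        ]
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite config values")


@dataclass
class GroundTruth:
    """Per-gene truth table plus module -> term assignments.

    ``genes`` columns: is_rhythmic (bool), is_subthreshold (bool), phase_zt
    (NaN for non-rhythmic), fold_change, module_id (empty string for
    unassigned genes).
    """

    genes: pd.DataFrame
    module_terms: dict[str, str] = field(default_factory=dict)

    @property
    def rhythmic_genes(self) -> set[str]:
        return set(self.genes.index[self.genes["is_rhythmic"]])

    @property
    def strong_rhythmic_genes(self) -> set[str]:
        m = self.genes["is_rhythmic"] & ~self.genes["is_subthreshold"]
        return set(self.genes.index[m])

    def module_members(self, module_id: str) -> set[str]:
        return set(self.genes.index[self.genes["module_id"] == module_id])

    @property
    def module_ids(self) -> list[str]:
        ids = self.genes["module_id"].unique()
        return sorted(i for i in ids if i)

    def write(self, path) -> None:
        self.genes.to_csv(path, sep="\t")


def _wrap24(x):
    return np.mod(x, 24.0)


def generate_expression(config: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a raw-fluorescence expression matrix and its ground truth.

    A rhythmic gene g follows, on the log2 scale,

        y_g(t) = b_g + (log2 fc_g)/2 * cos(2*pi*(t - phase_g)/period) + noise,

    with phases grouped into phase-coherent modules; non-rhythmic genes are
    flat plus noise.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    t = np.asarray(config.timepoints_h, dtype=float)
    zt = np.repeat(t, config.n_replicates)
    reps = np.tile(np.arange(1, config.n_replicates + 1), len(t))
    gene_ids = [f"g{i:04d}" for i in range(n)]

    n_rhythmic = int(round(config.frac_rhythmic * n))
    n_near = int(round(config.frac_near_rhythmic * n))
    if n_rhythmic + n_near > n:
        raise ValueError("rhythmic + near-rhythmic genes exceed n_genes")

    order = rng.permutation(n)
    strong_idx = order[:n_rhythmic]
    near_idx = order[n_rhythmic : n_rhythmic + n_near]
    flat_idx = order[n_rhythmic + n_near :]

    # module centres cluster at the two circular modes (mid-day / mid-night)
    # but distinct modules keep distinct peak times: within a mode they are
    # spread 3.5 h apart (plus jitter), emulating separate temporal programs
    mode = np.arange(config.n_modules) % 2
    centres = np.empty(config.n_modules)
    for which in (0, 1):
        idx = np.flatnonzero(mode == which)
        offsets = config.module_phase_spacing_h * (
            np.arange(len(idx)) - (len(idx) - 1) / 2.0
        )
        jitter = rng.uniform(-0.5, 0.5, size=len(idx))
        centres[idx] = config.phase_modes_zt[which] + offsets + jitter
    centres = _wrap24(centres)
    module_ids = [f"M{m:02d}" for m in range(config.n_modules)]

    phase = np.full(n, np.nan)
    fold = np.ones(n)
    module = np.array([""] * n, dtype=object)
    is_rhythmic = np.zeros(n, dtype=bool)
    is_sub = np.zeros(n, dtype=bool)

    half_w = config.module_phase_window_h / 2.0
    for k, gi in enumerate(strong_idx):
        m = k % config.n_modules
        phase[gi] = _wrap24(centres[m] + rng.uniform(-half_w, half_w))
        module[gi] = module_ids[m]
        is_rhythmic[gi] = True
    fc = config.fold_change_median * np.power(
        2.0, rng.normal(0.0, config.fold_change_spread, size=n_rhythmic)
    )
    fold[strong_idx] = np.maximum(fc, config.min_fold_change)

    for k, gi in enumerate(near_idx):
        m = k % config.n_modules
        phase[gi] = _wrap24(centres[m] + rng.uniform(-half_w, half_w))
        module[gi] = module_ids[m]
        is_rhythmic[gi] = True
        is_sub[gi] = True
        fold[gi] = config.near_fold_change

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    # a slice of flat genes never rises above the background floor
    n_below = int(round(config.frac_below_background * n))
    below_idx = flat_idx[:n_below]
    baseline[below_idx] = np.log2(config.background_floor) - 1.0

    amp = 0.5 * np.log2(fold)
    log2_vals = baseline[:, None] + rng.normal(
        0.0, config.noise_sd_log2, size=(n, len(zt))
    )
    rhythmic_mask = is_rhythmic
    cosines = np.cos(
        2 * np.pi * (zt[None, :] - phase[rhythmic_mask, None]) / config.period_h
    )
    log2_vals[rhythmic_mask] += amp[rhythmic_mask, None] * cosines
    # module-shared, replicate-consistent temporal fluctuation: distinguishes
    # modules that happen to share a peak phase, as distinct regulatory
    # programs would.  Projected orthogonal to {1, cos, sin} at the scanned
    # period so it carries co-expression signal without sinusoidal rhythm;
    # sub-threshold module members load it with a fixed sd, strong members in
    # proportion to their own amplitude.
    if config.module_wiggle_rel > 0 or config.near_wiggle_sd > 0:
        w = 2 * np.pi * t / config.period_h
        basis = np.column_stack([np.ones_like(t), np.cos(w), np.sin(w)])
        q, _ = np.linalg.qr(basis)
        wiggle = rng.normal(0.0, 1.0, size=(config.n_modules, len(t)))
        wiggle -= (wiggle @ q) @ q.T
        sd = wiggle.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        wiggle /= sd
        tp_index = np.searchsorted(t, zt)
        loading = np.where(
            is_sub, config.near_wiggle_sd, config.module_wiggle_rel * amp
        )
        for mi, mid in enumerate(module_ids):
            members = np.flatnonzero(module == mid)
            if len(members) == 0:
                continue
            log2_vals[members] += (
                loading[members, None] * wiggle[mi, tp_index][None, :]
            )

    values = pd.DataFrame(
        np.power(2.0, log2_vals),
        index=pd.Index(gene_ids, name="gene"),
        columns=[sample_label(z, r) for z, r in zip(zt, reps)],
    )
    matrix = ExpressionMatrix(values, zt=zt, replicate=reps, log2=False)
    truth = GroundTruth(
        pd.DataFrame(
            {
                "is_rhythmic": is_rhythmic,
                "is_subthreshold": is_sub,
                "phase_zt": phase,
                "fold_change": fold,
                "module_id": module,
            },
            index=pd.Index(gene_ids, name="gene"),
        )
    )
    return matrix, truth


def generate_annotations(
    truth: GroundTruth,
    n_terms: int = 20,
    signal: float = 0.9,
    noise_rate: float = 0.02,
    seed: int = 0,
) -> AnnotationMap:
    """Module-aligned functional annotations.

    Each module gets one dedicated term annotating a fraction ``signal`` of
    its members; the remaining terms are sprinkled over all genes at
    ``noise_rate`` per (gene, term) pair.  Genes receiving nothing stay
    unannotated, playing the role of uncharacterized genes.
    """
    if not (0.0 <= signal <= 1.0 and 0.0 <= noise_rate <= 1.0):
        raise ValueError("signal and noise_rate must lie in [0, 1]")
    modules = truth.module_ids
    if n_terms < len(modules):
        raise ValueError("need at least one term per module")
    rng = np.random.default_rng(seed)
    genes = list(truth.genes.index)
    pairs: list[tuple[str, str]] = []
    truth.module_terms = {}
    for k, m in enumerate(modules):
        term = f"T{k:03d}"
        truth.module_terms[m] = term
        members = sorted(truth.module_members(m))
        n_sig = int(round(signal * len(members)))
        chosen = rng.choice(len(members), size=n_sig, replace=False)
        pairs.extend((members[i], term) for i in sorted(chosen))
    background_terms = [f"T{k:03d}" for k in range(len(modules), n_terms)]
    if background_terms and noise_rate > 0:
        # a fraction noise_rate of genes carries one spurious background term
        hit = rng.random(len(genes)) < noise_rate
        term_idx = rng.integers(0, len(background_terms), size=len(genes))
        pairs.extend(
            (genes[g], background_terms[term_idx[g]]) for g in np.flatnonzero(hit)
        )
    return AnnotationMap.from_pairs(pairs)


def generate_reference_rhythmic_set(
    truth: GroundTruth, n: int, contamination: float = 0.0, seed: int = 0
) -> set[str]:
    """An external 'known rhythmic' reference list with controlled purity.

    Draws ``(1 - contamination) * n`` genes from the true rhythmic set and
    the rest from non-rhythmic genes.
    """
    if not (0.0 <= contamination <= 1.0):
        raise ValueError("contamination must lie in [0, 1]")
    if n > len(truth.genes):
        raise ValueError("n exceeds the number of genes")
    rng = np.random.default_rng(seed)
    rhythmic = sorted(truth.rhythmic_genes)
    other = sorted(set(truth.genes.index) - truth.rhythmic_genes)
    n_true = int(round((1.0 - contamination) * n))
    n_false = n - n_true
    if n_true > len(rhythmic) or n_false > len(other):
        raise ValueError("requested reference set exceeds available genes")
    picked = [rhythmic[i] for i in rng.choice(len(rhythmic), n_true, replace=False)]
    picked += [other[i] for i in rng.choice(len(other), n_false, replace=False)]
    return set(picked)
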