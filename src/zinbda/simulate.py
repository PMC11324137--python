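"""Semi-parametric two-group scATAC-seq count simulator.

Per-peak baseline (mu, p) pairs are sampled jointly (with replacement) from
a baseline table — preserving the empirical coupling between mean and
prevalence — and dispersions are drawn from a log-normal distribution with
hyperparameters matching genome-wide estimates (theta = 0.03, sigma = 0.57
by default). Group 1 keeps the baseline; for a chosen fraction of
differential peaks, group 2's parameters are multiplied by 2**log2fc for
half of them and divided for the other half, on the parameter set selected
by the scenario (mean, prevalence, dispersion, or all three). Counts are
then drawn from the ZINB generative model: a Bernoulli(p) structural zero,
otherwise a Gamma-Poisson (negative binomial) draw with mean mu and
dispersion phi.

When no baseline table is supplied, a built-in synthetic emulator draws
log mu from a normal distribution (median count 0.5) and couples p to mu
through a decreasing logistic curve plus noise, reproducing the sparse,
low-count regime of single-cell ATAC peaks and the negative mu-p coupling
seen in real estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import expit

from .shrinkage import ShrinkagePrior

logger = logging.getLogger(__name__)

__all__ = [
    "SCENARIOS",
    "SimConfig",
    "SimTruth",
    "draw_baseline",
    "synthetic_baseline",
    "apply_effect",
    "generate_counts",
    "simulate_dataset",
]

SCENARIOS = ("mean", "prevalence", "dispersion", "all")
_SCENARIO_PARAMS = {
    "mean": ("mu",),
    "prevalence": ("p",),
    "dispersion": ("phi",),
    "all": ("mu", "p", "phi"),
}
# Log-normal dispersion prior matching genome-wide estimates.
DEFAULT_PRIOR = ShrinkagePrior(theta=0.03, sigma=0.57)
P_CLIP = (0.01, 0.99)


@dataclass
class SimConfig:
    """Simulation settings; defaults mirror the benchmark design
    (4000 peaks, 100 cells per group, 20% differential peaks)."""

    n_peaks: int = 4000
    n_cells_per_group: int = 100
    prop_differential: float = 0.20
    scenario: str = "all"
    log2fc: float = 2.5
    baseline: object = "synthetic"   # DataFrame with mu, p columns or "synthetic"
    prior: ShrinkagePrior = field(default_factory=lambda: DEFAULT_PRIOR)
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.prop_differential <= 1.0):
            raise ValueError("prop_differential must lie in [0, 1]")
        if self.log2fc < 0:
            raise ValueError("log2fc must be non-negative")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    is_differential: np.ndarray        # bool per peak
    params_g1: pd.DataFrame            # columns p, mu, phi
    params_g2: pd.DataFrame
    direction: np.ndarray              # "multiplied"/"divided"/"" per peak

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "is_differential": self.is_differential.astype(int),
            "direction": self.direction,
        })
        for g, params in (("g1", self.params_g1), ("g2", self.params_g2)):
            for col in ("p", "mu", "phi"):
                df[f"{col}_{g}"] = params[col].to_numpy()
        return df


def synthetic_baseline(n_peaks: int, rng: np.random.Generator) -> pd.DataFrame:
    """Built-in (mu, p) emulator for sparse scATAC peak counts.

    mu is log-normal with median 0.5 counts and log-SD 1; the prevalence of
    structural zeros decreases with log mu through a logistic curve plus
    Gaussian noise, clipped to [0.01, 0.95].
    """
    log_mu = rng.normal(np.log(0.5), 1.0, size=n_peaks)
    p = expit(-(log_mu - np.log(0.5))) * 0.6 + rng.normal(0.0, 0.05, n_peaks)
    p = np.clip(p, 0.01, 0.95)
    return pd.DataFrame({"mu": np.exp(log_mu), "p": p})


def draw_baseline(n_peaks: int, baseline="synthetic",
                  prior: ShrinkagePrior = DEFAULT_PRIOR,
                  seed=None) -> pd.DataFrame:
    """Per-peak baseline parameter triples.

    (mu, p) pairs are sampled jointly with replacement from the baseline
    table (pairing preserved); phi = exp(Normal(theta, sigma)) is drawn
    independently.
    """
    rng = np.random.default_rng(seed)
    if isinstance(baseline, str) and baseline == "synthetic":
        table = synthetic_baseline(n_peaks, rng)
        idx = np.arange(n_peaks)
    else:
        table = pd.DataFrame(baseline)
        if table.empty:
            raise ValueError("baseline table must be non-empty")
        if not {"mu", "p"}.issubset(table.columns):
            raise ValueError("baseline table needs 'mu' and 'p' columns")
        idx = rng.integers(0, len(table), size=n_peaks)
    mu = table["mu"].to_numpy()[idx]
    p = table["p"].to_numpy()[idx]
    phi = np.exp(rng.normal(prior.theta, prior.sigma, size=n_peaks))
    return pd.DataFrame({"p": p, "mu": mu, "phi": phi})


def apply_effect(params: pd.DataFrame, config: SimConfig,
                 rng: np.random.Generator | None = None) -> SimTruth:
    """Inject fold changes into group 2 for the differential peaks.

    The scenario's parameter set is multiplied by 2**log2fc for half the
    differential peaks and divided for the other half (equal proportion,
    split sizes differing by at most one); the prevalence is clipped to
    [0.01, 0.99] after scaling.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(params)
    n_diff = int(round(config.prop_differential * n))
    diff_idx = rng.choice(n, size=n_diff, replace=False)
    n_mult = n_diff // 2
    mult_idx = diff_idx[:n_mult]
    div_idx = diff_idx[n_mult:]

    is_diff = np.zeros(n, dtype=bool)
    is_diff[diff_idx] = True
    direction = np.full(n, "", dtype=object)
    direction[mult_idx] = "multiplied"
    direction[div_idx] = "divided"

    g1 = params[["p", "mu", "phi"]].copy().reset_index(drop=True)
    g2 = g1.copy()
    factor = 2.0 ** config.log2fc
    for name in _SCENARIO_PARAMS[config.scenario]:
        vals = g2[name].to_numpy(copy=True)
        vals[mult_idx] *= factor
        vals[div_idx] /= factor
        if name == "p":
            clipped = (vals < P_CLIP[0]) | (vals > P_CLIP[1])
            n_clip = int(np.count_nonzero(clipped & is_diff))
            if n_clip:
                logger.info("prevalence clipped to %s for %d differential "
                            "peaks after fold change", P_CLIP, n_clip)
            vals = np.clip(vals, *P_CLIP)
        g2[name] = vals
    return SimTruth(is_differential=is_diff, params_g1=g1, params_g2=g2,
                    direction=np.asarray(direction))


def _draw_group(params: pd.DataFrame, n_cells: int,
                rng: np.random.Generator) -> np.ndarray:
    """ZINB draws for one group: structural-zero mask, then Gamma-Poisson."""
    p = params["p"].to_numpy()[:, None]
    mu = params["mu"].to_numpy()[:, None]
    phi = np.maximum(params["phi"].to_numpy(), 1e-12)[:, None]
    shape = (len(params), n_cells)
    # Gamma-Poisson mixture gives NB with Var = mu + mu^2 phi.
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi, size=shape)
    counts = rng.poisson(lam)
    structural = rng.random(shape) < p
    counts[structural] = 0
    return counts.astype(np.int64)


def generate_counts(truth: SimTruth, n_cells_per_group: int, seed=None):
    """Counts for both groups from the generative model.

    Returns (counts, groups): a peaks-by-cells integer matrix (group-1
    cells first) and the per-cell group labels.
    """
    rng = np.random.default_rng(seed)
    c1 = _draw_group(truth.params_g1, n_cells_per_group, rng)
    c2 = _draw_group(truth.params_g2, n_cells_per_group, rng)
    counts = np.hstack([c1, c2])
    groups = np.array(["group1"] * n_cells_per_group
                      + ["group2"] * n_cells_per_group)
    return counts, groups


def simulate_dataset(config: SimConfig):
    """Full simulation: baseline draw, effect injection, count generation.

    Returns (counts, groups, truth); all randomness flows from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    base = draw_baseline(config.n_peaks, config.baseline, config.prior,
                         seed=rng)
    truth = apply_effect(base, config, rng=rng)
    counts, groups = generate_counts(truth, config.n_cells_per_group,
                                     seed=rng)
    return counts, groups, truth


def to_sparse(counts: np.ndarray) -> sparse.csr_matrix:
    return sparse.csr_matrix(counts)
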