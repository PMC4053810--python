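"""Synthetic data generators with known ground truth.

Every other module is exercised against data produced here: flow-sorted
reference panels with planted cell-type marker probes, whole-tissue mixture
cohorts whose composition follows a monotone age trend with an inflection
near 40 years, confounded EWAS scenarios in which age acts on methylation
only through composition, and a two-cell-type brain design (NeuN+ neurons vs
NeuN- glia) with a titration series for validating the projection and the
CETS transform.

Probe baselines are drawn from a bimodal distribution concentrated near 0.1
and 0.9, mimicking the bimodality of CpG methylation.  Measurement noise is
Gaussian on the logit scale and mapped back through the inverse logit, which
keeps beta values in range and reproduces the heteroskedastic error of real
beta values (small near 0 and 1, largest near 0.5).  All betas are truncated
to [0.01, 0.99].  Every generator is driven by an explicit seed and returns a
:class:`GroundTruth` sufficient to score any downstream estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adjustment import CetsProfiles
from .matrix_io import BetaMatrix, SampleSheet
from .reference_builder import SortedReference

logger = logging.getLogger("methdecon")

BETA_LO, BETA_HI = 0.01, 0.99

#: default leukocyte panel, in declared order
BLOOD_CELL_TYPES = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran")

#: typical adult whole-blood proportions for the default panel
BLOOD_BASE_PROPORTIONS = {
    "CD8T": 0.10,
    "CD4T": 0.15,
    "NK": 0.07,
    "Bcell": 0.07,
    "Mono": 0.06,
    "Gran": 0.55,
}

#: direction and relative magnitude of the age trend per cell type; the
#: granulocyte fraction rises with age while T-cell fractions fall, and the
#: per-type swing is this weight times ``trend_amplitude``
BLOOD_TREND_WEIGHTS = {
    "CD8T": -0.25,
    "CD4T": -0.55,
    "NK": +0.05,
    "Bcell": -0.15,
    "Mono": +0.05,
    "Gran": +1.0,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate the six-cell-type, six-replicate sorted-blood design and
    a 200-sample, 5,000-probe whole-blood cohort.  ``within_sd`` and
    ``noise_sd`` are logit-scale Gaussian noise standard deviations for
    sorted replicates and mixture samples respectively; ``delta`` is the
    beta-scale marker effect; the age trend in composition is logistic with
    its inflection at ``inflection_age`` (years) and a total granulocyte
    swing of ``trend_amplitude``.  ``seed`` is mandatory.
    """

    seed: int
    cell_types: tuple[str, ...] = BLOOD_CELL_TYPES
    n_probes: int = 5000
    n_hyper_markers: int = 50
    n_hypo_markers: int = 50
    delta: float = 0.5
    within_sd: float = 0.01
    n_sorted_per_type: int = 6
    n_mixture_samples: int = 200
    age_range: tuple[float, float] = (1.0, 90.0)
    inflection_age: float = 40.0
    trend_width: float = 8.0
    trend_amplitude: float = 0.3
    noise_sd: float = 0.01
    # planted age-associated probes in the sorted reference (decoys the age
    # pre-filter must exclude); they also carry a cell-type effect so that,
    # unfiltered, they would enter the signature
    n_age_assoc_probes: int = 0
    reference_age_slope: float = 0.005
    # planted true age effects in mixture cohorts: per-cell-type slope
    # (beta units/year) applied to n_age_effect_probes probes
    n_age_effect_probes: int = 0
    age_effect_slope: float = 0.002
    age_effect_cell_type: str = "CD4T"
    # single categorical plate shift (logit scale) for confounded scenarios
    n_plates: int = 1
    plate_shift_sd: float = 0.0
    # inter-individual scatter of composition around the age trend
    # (lognormal multiplicative jitter on the raw shares)
    composition_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        self.cell_types = tuple(self.cell_types)

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)


@dataclass
class GroundTruth:
    """Everything needed to score estimates made from a simulated dataset."""

    seed: int
    reference_means: pd.DataFrame | None = None  # true per-type probe means
    markers: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    age_assoc_probes: list[str] = field(default_factory=list)
    proportions: pd.DataFrame | None = None  # true per-sample fractions
    ages: pd.Series | None = None
    age_effects: pd.DataFrame | None = None  # probe, cell_type, slope
    plate: pd.Series | None = None

    def marker_ids(self, cell_type: str | None = None) -> list[str]:
        types = [cell_type] if cell_type else list(self.markers)
        out: list[str] = []
        for ct in types:
            out.extend(self.markers[ct]["hyper"])
            out.extend(self.markers[ct]["hypo"])
        return out


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _logit(b: np.ndarray) -> np.ndarray:
    return np.log(b / (1.0 - b))


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _truncate(b: np.ndarray) -> np.ndarray:
    return np.clip(b, BETA_LO, BETA_HI)


def add_logit_noise(
    beta: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise on the logit scale, inverse-transformed and truncated."""
    if sd == 0:
        return _truncate(beta.copy())
    noisy = _inv_logit(_logit(_truncate(beta)) + rng.normal(0.0, sd, beta.shape))
    return _truncate(noisy)


def _bimodal_baselines(n: int, rng: np.random.Generator) -> np.ndarray:
    """Baseline probe means from a mixture favoring the 0.1/0.9 extremes."""
    low = rng.beta(2.0, 18.0, n)
    high = rng.beta(18.0, 2.0, n)
    pick_high = rng.random(n) < 0.5
    return _truncate(np.where(pick_high, high, low))


def _reference_mean_matrix(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, GroundTruth]:
    """True per-cell-type mean profiles with planted markers and age decoys."""
    K = config.n_cell_types
    per_type = config.n_hyper_markers + config.n_hypo_markers
    n_special = K * per_type + config.n_age_assoc_probes
    if n_special > config.n_probes:
        raise ValueError(
            f"n_probes={config.n_probes} too small for {n_special} planted probes"
        )
    probe_ids = pd.Index([f"cg{i:07d}" for i in range(config.n_probes)])
    base = _bimodal_baselines(config.n_probes, rng)
    mu = np.tile(base[:, None], (1, K))

    slots = rng.permutation(config.n_probes)[:n_special]
    pos = 0
    markers: dict[str, dict[str, list[str]]] = {}
    for k, ct in enumerate(config.cell_types):
        hyper = slots[pos : pos + config.n_hyper_markers]
        pos += config.n_hyper_markers
        hypo = slots[pos : pos + config.n_hypo_markers]
        pos += config.n_hypo_markers
        # re-seat marker baselines so the +/- delta shift stays in range
        mu[hyper, :] = rng.uniform(
            BETA_LO + 0.02, BETA_HI - config.delta - 0.02, len(hyper)
        )[:, None]
        mu[hyper, k] += config.delta
        mu[hypo, :] = rng.uniform(
            BETA_LO + config.delta + 0.02, BETA_HI - 0.02, len(hypo)
        )[:, None]
        mu[hypo, k] -= config.delta
        markers[ct] = {
            "hyper": list(probe_ids[hyper]),
            "hypo": list(probe_ids[hypo]),
        }

    age_probes = slots[pos : pos + config.n_age_assoc_probes]
    if len(age_probes):
        # decoys: marker-sized cell-type effect plus a real age slope
        targets = rng.integers(0, K, len(age_probes))
        mu[age_probes, :] = rng.uniform(
            BETA_LO + 0.02, BETA_HI - config.delta - 0.02, len(age_probes)
        )[:, None]
        mu[age_probes, targets] += config.delta

    means = pd.DataFrame(
        _truncate(mu), index=probe_ids, columns=list(config.cell_types)
    )
    truth = GroundTruth(
        seed=config.seed,
        reference_means=means,
        markers=markers,
        age_assoc_probes=list(probe_ids[age_probes]),
    )
    return means, truth


# ---------------------------------------------------------------------------
# sorted reference panel
# ---------------------------------------------------------------------------

def simulate_reference(
    config: SimulationConfig,
) -> tuple[SortedReference, GroundTruth]:
    """Simulate a flow-sorted reference panel.

    ``n_sorted_per_type`` subjects contribute one sample per cell type; ages
    (shared across a subject's samples) are drawn to resemble an adult donor
    panel with mean near 38 years.  Planted age-associated decoy probes drift
    with donor age in every cell type at ``reference_age_slope`` beta units
    per year.
    """
    rng = np.random.default_rng(config.seed)
    means, truth = _reference_mean_matrix(config, rng)

    n_rep = config.n_sorted_per_type
    donor_ages = np.clip(rng.normal(38.0, 13.6, n_rep), 20.0, 65.0)
    age_idx = means.index.get_indexer(truth.age_assoc_probes)

    cols: dict[str, np.ndarray] = {}
    labels, ages = {}, {}
    for ct in config.cell_types:
        mu_ct = means[ct].to_numpy()
        for r in range(n_rep):
            clean = mu_ct.copy()
            if len(age_idx):
                clean[age_idx] += config.reference_age_slope * (
                    donor_ages[r] - donor_ages.mean()
                )
            sid = f"{ct}_{r + 1}"
            cols[sid] = add_logit_noise(_truncate(clean), config.within_sd, rng)
            labels[sid] = ct
            ages[sid] = donor_ages[r]

    beta = BetaMatrix(values=pd.DataFrame(cols, index=means.index))
    ref = SortedReference(
        beta=beta, labels=pd.Series(labels), ages=pd.Series(ages)
    )
    truth.ages = pd.Series(ages)
    return ref, truth


# ---------------------------------------------------------------------------
# mixture cohorts
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def age_trend_proportions(
    ages: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Composition as a monotone logistic function of age.

    Each cell type's raw share is its adult baseline plus a logistic ramp in
    age (inflection at ``inflection_age``, scale ``trend_width`` years) with
    a per-type signed weight; shares are floored at 1% and renormalized to
    the simplex.  When an ``rng`` is supplied, lognormal jitter of scale
    ``composition_noise_sd`` models inter-individual scatter around the
    trend; without it the curve is deterministic.
    """
    s = _sigmoid((np.asarray(ages, float) - config.inflection_age) / config.trend_width)
    raw = np.empty((len(s), config.n_cell_types))
    for k, ct in enumerate(config.cell_types):
        base = BLOOD_BASE_PROPORTIONS.get(ct, 1.0 / config.n_cell_types)
        weight = BLOOD_TREND_WEIGHTS.get(ct, 0.0)
        raw[:, k] = base + weight * config.trend_amplitude * (s - 0.5)
    raw = np.maximum(raw, 0.01)
    if rng is not None and config.composition_noise_sd > 0:
        raw = raw * np.exp(
            rng.normal(0.0, config.composition_noise_sd, raw.shape)
        )
    return pd.DataFrame(
        raw / raw.sum(axis=1, keepdims=True), columns=list(config.cell_types)
    )


def simulate_mixtures(
    means: pd.DataFrame,
    config: SimulationConfig,
    mode: str = "dirichlet",
    alpha: float | np.ndarray = 1.0,
    ages: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[BetaMatrix, GroundTruth]:
    """Whole-tissue samples as weighted averages of the cell-type profiles.

    ``mode='dirichlet'`` draws proportions from Dirichlet(alpha);
    ``mode='age_trend'`` uses :func:`age_trend_proportions` at ages drawn
    uniformly over ``config.age_range`` (or supplied).  Sample beta is the
    mixture means @ w plus logit-scale noise; the construction is exactly
    linear in the proportions before noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_mixture_samples
    K = means.shape[1]
    if mode == "dirichlet":
        a = np.broadcast_to(np.asarray(alpha, float), (K,))
        W = rng.dirichlet(a, size=n)
        ages_arr = None
    elif mode == "age_trend":
        if ages is None:
            ages_arr = rng.uniform(*config.age_range, n)
        else:
            ages_arr = np.asarray(ages, float)
            n = len(ages_arr)
        W = age_trend_proportions(ages_arr, config, rng).to_numpy()
    else:
        raise ValueError(f"unknown mixture mode: {mode!r}")

    sample_ids = pd.Index([f"mix_{i + 1:04d}" for i in range(n)])
    pure = means.to_numpy() @ W.T  # probes x samples, exactly linear in w
    noisy = add_logit_noise(pure, config.noise_sd, rng)
    beta = BetaMatrix(
        values=pd.DataFrame(noisy, index=means.index, columns=sample_ids)
    )
    truth = GroundTruth(
        seed=config.seed,
        reference_means=means,
        proportions=pd.DataFrame(W, index=sample_ids, columns=means.columns),
        ages=None if ages_arr is None else pd.Series(ages_arr, index=sample_ids),
    )
    return beta, truth


# ---------------------------------------------------------------------------
# confounded EWAS scenarios
# ---------------------------------------------------------------------------

def simulate_confounded_ewas(
    config: SimulationConfig,
) -> tuple[BetaMatrix, SampleSheet, GroundTruth]:
    """A whole-blood cohort in which age drives composition.

    Composition follows the age-trend model, so any probe whose cell-type
    means differ (the planted markers) acquires a marginal age association in
    the mixed tissue without any within-cell-type age effect — the
    false-positive mechanism.  Optionally, ``n_age_effect_probes`` probes
    receive a genuine within-cell-type age slope (``age_effect_slope`` beta
    units/year in ``age_effect_cell_type``), whose mixed-tissue marginal
    slope is the product of the slope and that type's mean proportion.  A
    plate shift (single categorical logit offset) can be layered on.
    """
    rng = np.random.default_rng(config.seed)
    means, truth = _reference_mean_matrix(config, rng)
    n = config.n_mixture_samples
    ages = rng.uniform(*config.age_range, n)
    W = age_trend_proportions(ages, config, rng).to_numpy()
    sample_ids = pd.Index([f"s_{i + 1:04d}" for i in range(n)])

    pure = means.to_numpy() @ W.T  # probes x samples

    age_effects = None
    if config.n_age_effect_probes:
        candidates = means.index[~means.index.isin(truth.marker_ids())]
        chosen = rng.choice(
            len(candidates), config.n_age_effect_probes, replace=False
        )
        probes = candidates[np.sort(chosen)]
        k = list(config.cell_types).index(config.age_effect_cell_type)
        rows = means.index.get_indexer(probes)
        centered_age = ages - ages.mean()
        # the affected cell type's profile drifts with the sample's age
        pure[rows, :] += config.age_effect_slope * centered_age[None, :] * W.T[k]
        age_effects = pd.DataFrame(
            {
                "probe_id": probes,
                "cell_type": config.age_effect_cell_type,
                "slope": config.age_effect_slope,
            }
        ).set_index("probe_id")

    plate = None
    if config.n_plates > 1:
        plate_labels = np.array(
            [f"plate{i % config.n_plates + 1}" for i in range(n)]
        )
        shifts = rng.normal(0.0, config.plate_shift_sd, config.n_plates)
        offsets = shifts[
            np.array([int(p[5:]) - 1 for p in plate_labels])
        ]
        pure = _inv_logit(_logit(_truncate(pure)) + offsets[None, :])
        plate = pd.Series(plate_labels, index=sample_ids, name="plate")

    noisy = add_logit_noise(_truncate(pure), config.noise_sd, rng)
    beta = BetaMatrix(
        values=pd.DataFrame(noisy, index=means.index, columns=sample_ids)
    )
    sheet_tab = pd.DataFrame({"age": ages}, index=sample_ids)
    if plate is not None:
        sheet_tab["plate"] = plate
    sheet_tab.index.name = "sample_id"
    sheet = SampleSheet(table=sheet_tab)

    truth.proportions = pd.DataFrame(
        W, index=sample_ids, columns=means.columns
    )
    truth.ages = pd.Series(ages, index=sample_ids)
    truth.age_effects = age_effects
    truth.plate = plate
    return beta, sheet, truth


def simulate_sorted_cohort(
    truth: GroundTruth, config: SimulationConfig
) -> dict[str, BetaMatrix]:
    """Sorted-cell samples at the same ages as a confounded cohort.

    Returns, per cell type, a beta matrix of pure-population samples for the
    cohort's subjects, carrying only the genuine within-cell-type age effects
    from the ground truth (none under the pure-confounding null).  Regressing
    these on age is the design in which composition cannot confound.
    """
    rng = np.random.default_rng(config.seed + 1)
    means = truth.reference_means
    ages = truth.ages.to_numpy()
    centered = ages - ages.mean()
    out = {}
    for ct in config.cell_types:
        profile = np.tile(means[ct].to_numpy()[:, None], (1, len(ages)))
        if truth.age_effects is not None:
            affected = truth.age_effects[truth.age_effects["cell_type"] == ct]
            rows = means.index.get_indexer(affected.index)
            profile[rows, :] += (
                affected["slope"].to_numpy()[:, None] * centered[None, :]
            )
        noisy = add_logit_noise(_truncate(profile), config.noise_sd, rng)
        out[ct] = BetaMatrix(
            values=pd.DataFrame(
                noisy, index=means.index, columns=truth.ages.index
            )
        )
    return out


# ---------------------------------------------------------------------------
# two-cell-type brain design (NeuN+/NeuN-)
# ---------------------------------------------------------------------------

@dataclass
class BrainSimulation:
    """Outputs of the two-cell-type design: a sorted NeuN+/NeuN- reference,
    a 10%-90% neuron titration series with its designed fractions, and the
    profile decomposition for the CETS transform."""

    reference: SortedReference
    titration: BetaMatrix
    designed_pi: pd.Series
    profiles: CetsProfiles
    truth: GroundTruth


def simulate_two_celltype_brain(
    config: SimulationConfig,
    n_individuals: int = 20,
    deviation_sd: float = 0.02,
    deviations_equal: bool = False,
    titration_fractions: np.ndarray | None = None,
) -> BrainSimulation:
    """Neuron/glia design with individual-level profile deviations.

    Each of ``n_individuals`` has its own neuron and glia profiles deviating
    from the population averages by beta-scale Gaussian offsets of sd
    ``deviation_sd``; with ``deviations_equal`` the two cell types share the
    same offset (the special case in which the CETS transform is unbiased).
    The titration series mixes the average profiles at neuron fractions
    10%..90% (by default) with logit-scale noise ``config.noise_sd``.
    """
    rng = np.random.default_rng(config.seed)
    cfg2 = replace(
        config,
        cell_types=("NeuN_pos", "NeuN_neg"),
        n_age_assoc_probes=0,
        seed=config.seed,
    )
    means, truth = _reference_mean_matrix(cfg2, rng)
    mu_bar_N = means["NeuN_pos"].to_numpy()
    mu_bar_G = means["NeuN_neg"].to_numpy()

    # sorted reference samples of each pure population
    cols, labels = {}, {}
    for ct in cfg2.cell_types:
        mu_ct = means[ct].to_numpy()
        for r in range(config.n_sorted_per_type):
            sid = f"{ct}_{r + 1}"
            cols[sid] = add_logit_noise(mu_ct, config.within_sd, rng)
            labels[sid] = ct
    reference = SortedReference(
        beta=BetaMatrix(values=pd.DataFrame(cols, index=means.index)),
        labels=pd.Series(labels),
    )

    # titration series of the average profiles
    if titration_fractions is None:
        titration_fractions = np.arange(0.1, 0.91, 0.1)
    pi_t = np.round(np.asarray(titration_fractions, float), 10)
    tit_ids = pd.Index([f"mix_{int(round(p * 100))}pct" for p in pi_t])
    mix = np.outer(mu_bar_N, pi_t) + np.outer(mu_bar_G, 1.0 - pi_t)
    titration = BetaMatrix(
        values=pd.DataFrame(
            add_logit_noise(mix, config.noise_sd, rng),
            index=means.index,
            columns=tit_ids,
        )
    )

    # individual-level profiles for the CETS decomposition
    lo = np.maximum(BETA_LO - mu_bar_N, BETA_LO - mu_bar_G)
    hi = np.minimum(BETA_HI - mu_bar_N, BETA_HI - mu_bar_G)
    dev_N = np.clip(
        rng.normal(0.0, deviation_sd, (n_individuals, config.n_probes)), lo, hi
    )
    if deviations_equal:
        dev_G = dev_N
    else:
        dev_G = np.clip(
            rng.normal(0.0, deviation_sd, (n_individuals, config.n_probes)), lo, hi
        )
    pi = rng.uniform(0.1, 0.9, n_individuals)
    eps = (
        rng.normal(0.0, config.noise_sd * 0.25, (n_individuals, config.n_probes))
        if config.noise_sd > 0
        else np.zeros((n_individuals, config.n_probes))
    )
    profiles = CetsProfiles.assemble(
        pi=pi,
        mu_N=mu_bar_N[None, :] + dev_N,
        mu_G=mu_bar_G[None, :] + dev_G,
        mu_bar_N=mu_bar_N,
        mu_bar_G=mu_bar_G,
        eps=eps,
    )
    return BrainSimulation(
        reference=reference,
        titration=titration,
        designed_pi=pd.Series(pi_t, index=tit_ids, name="neun_pos_fraction"),
        profiles=profiles,
        truth=truth,
    )
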