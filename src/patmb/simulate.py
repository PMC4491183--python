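"""Synthetic longitudinal cohorts with pulsed antibiotic exposure and a diet shift.

The generator emulates the statistical structure of an early-life
pulsed-antibiotic-treatment (PAT) mouse study: four treatment groups
(control, amoxicillin, tylosin, mixture), three short antibiotic courses at
days 10-15, 28-31 and 37-40 of life, a switch from normal chow to high-fat
diet (HFD) at day 41, and roughly 14 timed faecal samples per mouse with
overdispersed sequencing depth.

Community composition is built from four OTU guilds:

* **succession pairs** — an "early-life" OTU whose expected proportion
  decays logistically with age, paired with a "late-life" OTU that rises
  with the mirrored logistic, so each pair's combined mass is constant and
  community evenness has no systematic age trend (mirroring the flat
  control alpha-diversity trajectory);
* **diet pairs** — a low-abundance OTU whose weight is swapped with a
  high-abundance partner when the diet shifts; the post-shift weight
  multiset is a permutation of the pre-shift one, so the diet shift moves
  probability mass across taxa (a large community shift) without changing
  expected diversity;
* **stable** OTUs with constant weights;
* two designated **bloom** OTUs (Akkermansia-like and
  Enterobacteriaceae-like) that expand by a fold-change during antibiotic
  pulses.

Antibiotic courses act four ways: an **evenness loss** (proportions raised
to a power > 1, concentrating the community), a **bloom** of the
antibiotic's bloom OTU, a **depletion of the late-successional guild**
(the compositional face of arrested maturation), and a **maturation lag**
— the succession clock and the diet response are evaluated at
(day - accumulated lag), so exposed mice look younger than their
chronological age and respond late to the diet shift. Community
distortions are step-shaped: full strength through the course and a
per-antibiotic persistence window, then off, so exposed communities occupy
discrete states. Tylosin's distortion is strong, slow to clear and its lag
permanent; amoxicillin's clears within days and its lag recovers within
two weeks; the mixture group receives tylosin/amoxicillin/tylosin.

Counts are drawn from a Dirichlet-multinomial: p ~ Dirichlet(theta * expected),
counts ~ Multinomial(depth, p), with per-sample depth log-normal.

Every sample carries ground truth — true maturity age, a planted community
state in {1: pre-diet baseline, 2: mildly perturbed, 3: markedly perturbed,
4: post-diet} and the expected proportion vector — for parameter-recovery
testing of the downstream analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import CohortMetadata, GROUPS, OtuTable

__all__ = [
    "AntibioticEffect",
    "distort_profile",
    "SimulationConfig",
    "SimulationTruth",
    "ExposureState",
    "exposure_state",
    "maturation_profile",
    "apply_perturbation",
    "expected_profile",
    "sample_counts",
    "simulate_cohort",
]


@dataclass(frozen=True)
class AntibioticEffect:
    """Per-course effect of one antibiotic.

    evenness_loss : factor in (0, 1]; proportions are raised to the power
        1/evenness_loss while the effect is active (1 = no effect).
    maturation_lag : days of developmental delay accumulated per course.
    lag_recovery_days : days over which the lag decays back to zero after a
        course ends; None = the lag is permanent.
    persistence_days : days after a course ends during which the community
        distortion (evenness loss and bloom) remains at full strength; the
        distortion then switches off, so the community occupies a discrete
        perturbed state rather than a continuum.
    bloom_fold : fold-change applied to the antibiotic's bloom OTU while
        the course effect is active.
    late_depletion : factor in (0, 1] multiplying late-successional guild
        OTUs while the effect is active; values < 1 preferentially deplete
        the mature-community members, the compositional face of delayed
        development.
    """

    evenness_loss: float = 1.0
    maturation_lag: float = 0.0
    lag_recovery_days: float | None = None
    persistence_days: float = 10.0
    bloom_fold: float = 1.0
    late_depletion: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.evenness_loss <= 1.0):
            raise ValueError("evenness_loss must be in (0, 1]")
        if self.maturation_lag < 0:
            raise ValueError("maturation_lag must be >= 0")
        if self.persistence_days < 0:
            raise ValueError("persistence_days must be >= 0")
        if self.bloom_fold < 1:
            raise ValueError("bloom_fold must be >= 1")
        if not (0.0 < self.late_depletion <= 1.0):
            raise ValueError("late_depletion must be in (0, 1]")


def _default_antibiotics() -> dict[str, AntibioticEffect]:
    return {
        "tylosin": AntibioticEffect(
            evenness_loss=0.65,
            maturation_lag=6.0,
            lag_recovery_days=None,
            persistence_days=12.0,
            bloom_fold=5.0,
            late_depletion=0.30,
        ),
        "amoxicillin": AntibioticEffect(
            evenness_loss=0.75,
            maturation_lag=4.0,
            lag_recovery_days=14.0,
            persistence_days=6.0,
            bloom_fold=14.0,
            late_depletion=0.70,
        ),
    }


def _default_schedules() -> dict[str, tuple[str | None, ...]]:
    return {
        "control": (None, None, None),
        "amoxicillin": ("amoxicillin", "amoxicillin", "amoxicillin"),
        "tylosin": ("tylosin", "tylosin", "tylosin"),
        "mixture": ("tylosin", "amoxicillin", "tylosin"),
    }


_LINEAGES = {
    "early": [
        "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; f__Lactobacillaceae; g__Lactobacillus",
        "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; f__Enterococcaceae; g__Enterococcus",
        "k__Bacteria; p__Actinobacteria; c__Actinobacteria; o__Bifidobacteriales; f__Bifidobacteriaceae; g__Bifidobacterium",
    ],
    "late": [
        "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Lachnospiraceae; g__Blautia",
        "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; f__Bacteroidaceae; g__Bacteroides",
        "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Oscillospiraceae; g__Oscillibacter",
    ],
    "diet_up": [
        "k__Bacteria; p__Firmicutes; c__Erysipelotrichia; o__Erysipelotrichales; f__Erysipelotrichaceae; g__Allobaculum",
        "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Ruminococcaceae; g__Ruminococcus",
        "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; f__Streptococcaceae; g__Streptococcus",
    ],
    "diet_down": [
        "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; f__Rikenellaceae; g__Alistipes",
        "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; f__Prevotellaceae; g__Prevotella",
        "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; f__Porphyromonadaceae; g__Parabacteroides",
    ],
    "stable": [
        "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; f__Muribaculaceae; g__Muribaculum",
        "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Clostridiaceae; g__Clostridium",
        "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Eubacteriaceae; g__Eubacterium",
        # no family assignment: exercises the "<order> other" bucket downstream
        "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__; g__",
    ],
    "bloom_tylosin": (
        "k__Bacteria; p__Verrucomicrobia; c__Verrucomicrobiae; o__Verrucomicrobiales; f__Verrucomicrobiaceae; g__Akkermansia"
    ),
    "bloom_amoxicillin": (
        "k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; o__Enterobacteriales; f__Enterobacteriaceae; g__Escherichia"
    ),
}


@dataclass(frozen=True)
class GuildLayout:
    """Resolved OTU guild structure for one configuration (deterministic in seed)."""

    otu_ids: tuple[str, ...]
    taxonomy: dict[str, str]
    guild: tuple[str, ...]  # per OTU: early/late/diet_up/diet_down/stable/bloom_*
    base_weights: np.ndarray  # pre-shift expected weights (sum 1) at "reference"
    post_diet_weights: np.ndarray  # weights with the diet permutation applied
    succession_pairs: tuple[tuple[int, int], ...]  # (early_idx, late_idx)
    midpoints: np.ndarray  # logistic midpoint day per succession pair
    pair_amplitudes: np.ndarray  # combined weight per succession pair
    bloom_index: dict[str, int]  # antibiotic name -> OTU index
    solo_succession: tuple[tuple[int, float, float, int], ...] = ()
    # unpaired mode: (otu index, amplitude, midpoint, +1 rising / -1 falling)


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic PAT cohort.

    Defaults encode the emulated study design: 4 groups x 3 mice, 14
    sampling days spanning days 21-142 of life, antibiotic courses at days
    10-15, 28-31 and 37-40, diet switch at day 41, log-normal depth around
    3,500 reads (a scaled-down sequencing effort), Dirichlet-multinomial
    overdispersion, and 4 planted community states.
    """

    n_mice_per_group: dict[str, int] = field(
        default_factory=lambda: {g: 3 for g in GROUPS}
    )
    sampling_days: tuple[int, ...] = (
        21, 25, 29, 33, 36, 40, 42, 45, 50, 57, 70, 90, 115, 142,
    )
    pulse_windows: tuple[tuple[int, int], ...] = ((10, 15), (28, 31), (37, 40))
    antibiotics: dict[str, AntibioticEffect] = field(
        default_factory=_default_antibiotics
    )
    group_schedules: dict[str, tuple[str | None, ...]] = field(
        default_factory=_default_schedules
    )
    diet_switch_day: int = 41
    diet_fold: float = 4.0
    n_otus: int = 100
    n_succession_pairs: int = 15
    n_diet_pairs: int = 10
    succession_mass: float = 0.10
    diet_mass: float = 0.25
    succession_scale_days: float = 9.0
    paired_succession: bool = True
    depth_mean: float = 3500.0
    depth_sd: float = 1500.0
    min_depth: int = 1200
    overdispersion: float = 1000.0
    n_states: int = 4
    major_evenness_threshold: float = 0.70
    mild_evenness_threshold: float = 0.97
    seed: int = 0

    def __post_init__(self) -> None:
        days = np.asarray(self.sampling_days)
        if np.any(np.diff(days) <= 0):
            raise ValueError("sampling_days must be strictly increasing")
        windows = sorted(self.pulse_windows)
        for (s, e) in windows:
            if e < s:
                raise ValueError(f"pulse window ({s},{e}) has end before start")
        for (_, e1), (s2, _) in zip(windows, windows[1:]):
            if s2 <= e1:
                raise ValueError("pulse windows must be non-overlapping and ordered")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be > 0")
        if self.diet_fold < 1:
            raise ValueError("diet_fold must be >= 1")
        if 2 * (self.n_succession_pairs + self.n_diet_pairs) + 2 > self.n_otus:
            raise ValueError("n_otus too small for the requested guild counts")
        unknown = set(self.n_mice_per_group) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")
        for g, sched in self.group_schedules.items():
            if len(sched) != len(self.pulse_windows):
                raise ValueError(f"schedule for {g} must list one entry per pulse")
            for ab in sched:
                if ab is not None and ab not in self.antibiotics:
                    raise ValueError(f"unknown antibiotic {ab!r} in {g} schedule")

    @cached_property
    def layout(self) -> GuildLayout:
        return _build_layout(self)

    @property
    def diet_effect(self) -> dict[str, float]:
        """Per-OTU fold-change defining the post-switch community state."""
        lay = self.layout
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = np.where(
                lay.base_weights > 0, lay.post_diet_weights / lay.base_weights, 1.0
            )
        return {
            o: float(f)
            for o, f, g in zip(lay.otu_ids, fold, lay.guild)
            if g in ("diet_up", "diet_down")
        }

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _build_layout(cfg: SimulationConfig) -> GuildLayout:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA11]))
    n_succ = cfg.n_succession_pairs
    n_diet = cfg.n_diet_pairs
    n_bloom = 2
    n_stable = cfg.n_otus - 2 * n_succ - 2 * n_diet - n_bloom

    otu_ids: list[str] = []
    guild: list[str] = []
    taxonomy: dict[str, str] = {}

    def add(g: str, lineage: str) -> int:
        idx = len(otu_ids)
        oid = f"OTU_{idx + 1:04d}"
        otu_ids.append(oid)
        guild.append(g)
        taxonomy[oid] = lineage
        return idx

    # succession pairs: mirrored logistics, staggered midpoints
    # midpoints extend past both ends of the sampling range so the summed
    # pair mixedness (hence expected Shannon) is flat across sampled days
    lo = cfg.sampling_days[0] - 15
    hi = cfg.sampling_days[-1] + 15
    if not cfg.paired_succession:
        # solo mode: each of the 2*n_succ OTUs follows its own logistic so
        # no two age predictors are collinear; midpoints stay interior to
        # the sampling range where the trajectory actually moves
        lo, hi = cfg.sampling_days[0] + 5, cfg.sampling_days[-1] - 15
        n_solo = 2 * n_succ
        mids = np.linspace(lo, hi, n_solo) if n_solo else np.empty(0)
        amps_solo = rng.lognormal(0.0, 0.5, size=n_solo)
        if n_solo:
            amps_solo *= cfg.succession_mass / amps_solo.sum()
        solo = []
        for i in range(n_solo):
            sign = -1 if i % 2 == 0 else 1
            g = "early" if sign < 0 else "late"
            idx = add(g, _LINEAGES[g][i % 3])
            solo.append((idx, float(amps_solo[i]), float(mids[i]), sign))
        midpoints, amps, pairs = np.empty(0), np.empty(0), []
    else:
        solo = []
        midpoints = np.linspace(lo, hi, n_succ) if n_succ else np.empty(0)
        amps = rng.lognormal(0.0, 0.5, size=n_succ) if n_succ else np.empty(0)
        if n_succ:
            amps *= cfg.succession_mass / amps.sum()
        pairs = []
        for i in range(n_succ):
            e = add("early", _LINEAGES["early"][i % 3])
            l = add("late", _LINEAGES["late"][i % 3])
            pairs.append((e, l))

    # diet pairs: weight swap at the switch
    diet_lo = rng.lognormal(0.0, 0.4, size=n_diet) if n_diet else np.empty(0)
    if n_diet:
        total = (diet_lo * (1.0 + cfg.diet_fold)).sum()
        diet_lo *= cfg.diet_mass / total
    diet_idx = []
    for i in range(n_diet):
        u = add("diet_up", _LINEAGES["diet_up"][i % 3])
        d = add("diet_down", _LINEAGES["diet_down"][i % 3])
        diet_idx.append((u, d))

    bloom_index = {
        "tylosin": add("bloom_tylosin", _LINEAGES["bloom_tylosin"]),
        "amoxicillin": add("bloom_amoxicillin", _LINEAGES["bloom_amoxicillin"]),
    }

    stable_idx = [
        add("stable", _LINEAGES["stable"][i % len(_LINEAGES["stable"])])
        for i in range(n_stable)
    ]

    w = np.zeros(cfg.n_otus)
    post = np.zeros(cfg.n_otus)
    # succession pairs carry their amplitude jointly; the split between the
    # early and late member is age-dependent (handled in maturation_profile),
    # base_weights records the pair total on the early slot for bookkeeping
    for (e, l), a in zip(pairs, amps):
        w[e] = a / 2.0
        w[l] = a / 2.0
    for idx, a, _m, _sign in solo:
        w[idx] = a / 2.0
    for (u, d), wl in zip(diet_idx, diet_lo):
        w[u] = wl
        w[d] = wl * cfg.diet_fold
    stable_mass = max(0.0, 1.0 - cfg.succession_mass - cfg.diet_mass)
    bloom_share = 0.12  # of the stable mass, split over the two bloom OTUs
    w[bloom_index["tylosin"]] = stable_mass * bloom_share * 0.55
    w[bloom_index["amoxicillin"]] = stable_mass * bloom_share * 0.45
    if stable_idx:
        sw = rng.lognormal(0.0, 1.0, size=len(stable_idx))
        sw *= stable_mass * (1.0 - bloom_share) / sw.sum()
        w[stable_idx] = sw

    post[:] = w
    for (u, d) in diet_idx:
        post[u], post[d] = w[d], w[u]  # permutation: expected diversity unchanged

    return GuildLayout(
        otu_ids=tuple(otu_ids),
        taxonomy=taxonomy,
        guild=tuple(guild),
        base_weights=w / w.sum(),
        post_diet_weights=post / post.sum(),
        succession_pairs=tuple(pairs),
        midpoints=midpoints,
        pair_amplitudes=amps,
        bloom_index=bloom_index,
        solo_succession=tuple(solo),
    )


# ---------------------------------------------------------------------------
# expected community profiles


def maturation_profile(day: float, config: SimulationConfig) -> np.ndarray:
    """Deterministic expected community at developmental age ``day``.

    Succession pairs split their joint mass between the early member
    (logistic decay) and the late member (mirrored logistic rise) around
    the pair's midpoint; diet-responsive weights swap once ``day`` passes
    the switch day; stable and bloom OTUs keep constant weights. Returns a
    vector on the simplex.
    """
    lay = config.layout
    w = (
        lay.post_diet_weights if day >= config.diet_switch_day else lay.base_weights
    ).copy()
    s = config.succession_scale_days
    for (e, l), a, m in zip(lay.succession_pairs, lay.pair_amplitudes, lay.midpoints):
        pair_total = w[e] + w[l]
        frac_early = float(expit((m - day) / s))
        w[e] = pair_total * frac_early
        w[l] = pair_total * (1.0 - frac_early)
    for idx, a, m, sign in lay.solo_succession:
        w[idx] = a * float(expit(-sign * (m - day) / s))
    return w / w.sum()


@dataclass(frozen=True)
class ExposureState:
    """Accumulated antibiotic exposure of one mouse at one day."""

    accumulated_lag: float
    evenness_factor: float  # current effective factor in (0, 1]
    bloom_folds: dict[int, float]  # OTU index -> current fold (> 1 when active)
    late_depletion: float  # current factor multiplying late-guild OTUs
    in_pulse: bool


def exposure_state(day: float, group: str, config: SimulationConfig) -> ExposureState:
    """Lag, evenness factor and bloom folds for ``group`` at ``day``."""
    schedule = config.group_schedules.get(group, ())
    lag = 0.0
    evenness = 1.0
    late_dep = 1.0
    blooms: dict[int, float] = {}
    in_pulse = False
    for (start, end), ab_name in zip(config.pulse_windows, schedule):
        if ab_name is None or day < start:
            continue
        ab = config.antibiotics[ab_name]
        span = max(end - start, 1)
        if day <= end:
            frac = (day - start) / span  # lag ramps up across the course
            lag += ab.maturation_lag * frac
            in_pulse = True
            active = True
        else:
            since = day - end
            lag_full = ab.maturation_lag
            if ab.lag_recovery_days is None:
                lag += lag_full
            else:
                lag += lag_full * max(0.0, 1.0 - since / ab.lag_recovery_days)
            active = since <= ab.persistence_days
        if active:
            evenness = min(evenness, ab.evenness_loss)
            late_dep = min(late_dep, ab.late_depletion)
            if ab.bloom_fold > 1.0:
                idx = config.layout.bloom_index[ab_name]
                blooms[idx] = max(blooms.get(idx, 1.0), ab.bloom_fold)
    return ExposureState(lag, evenness, blooms, late_dep, in_pulse)


def apply_perturbation(
    day: float, exposure: ExposureState, config: SimulationConfig
) -> np.ndarray:
    """Expected community of an exposed mouse at chronological ``day``.

    The maturation clock (and with it the diet response) is evaluated at
    ``day - accumulated_lag``; late-successional OTUs are multiplied by the
    current late-depletion factor; proportions are then raised to the power
    1/evenness_factor and renormalized (concentrating the community when
    the factor is < 1), and bloom OTUs are multiplied by their current
    fold-change and renormalized.
    """
    profile = maturation_profile(day - exposure.accumulated_lag, config)
    late_mask = np.array([g == "late" for g in config.layout.guild])
    return distort_profile(
        profile,
        evenness_factor=exposure.evenness_factor,
        bloom_folds=exposure.bloom_folds,
        late_depletion=exposure.late_depletion,
        late_mask=late_mask,
    )


def distort_profile(
    profile: np.ndarray,
    evenness_factor: float = 1.0,
    bloom_folds: dict[int, float] | None = None,
    late_depletion: float = 1.0,
    late_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Apply the perturbation arithmetic to an arbitrary simplex vector.

    Order of operations: late-guild depletion, evenness power transform
    (p -> p**(1/factor), renormalized), then bloom fold-changes,
    renormalized. With factor 1, no blooms and no depletion this is the
    identity.
    """
    out = np.asarray(profile, dtype=float).copy()
    if late_depletion < 1.0 and late_mask is not None:
        out[late_mask] *= late_depletion
        out = out / out.sum()
    if evenness_factor < 1.0:
        out = out ** (1.0 / evenness_factor)
        out = out / out.sum()
    if bloom_folds:
        for idx, fold in bloom_folds.items():
            out[idx] *= fold
        out = out / out.sum()
    return out


def _true_state(day: float, exposure: ExposureState, config: SimulationConfig) -> int:
    """Planted community state: 1 baseline, 2 mild, 3 major, 4 post-diet."""
    e = exposure.evenness_factor
    if e < config.major_evenness_threshold:
        return 3
    diet_shifted = (day - exposure.accumulated_lag) >= config.diet_switch_day
    if diet_shifted:
        return 4
    if e < config.mild_evenness_threshold:
        return 2
    return 1


def expected_profile(
    day: float, group: str, config: SimulationConfig
) -> tuple[np.ndarray, ExposureState, int]:
    """Expected proportions, exposure state and planted state for one sample."""
    exposure = exposure_state(day, group, config)
    profile = apply_perturbation(day, exposure, config)
    return profile, exposure, _true_state(day, exposure, config)


# ---------------------------------------------------------------------------
# count sampling


def sample_counts(
    expected: np.ndarray,
    depth: int,
    theta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Dirichlet-multinomial draw: p ~ Dir(theta*expected), counts ~ Mult(depth, p)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    expected = np.asarray(expected, dtype=float)
    p = rng.dirichlet(theta * expected)
    # gamma underflow can zero-out the whole draw for tiny alphas; guard
    if not np.isfinite(p).all() or p.sum() <= 0:
        p = expected
    return rng.multinomial(int(depth), p / p.sum())


@dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort, aligned with the sample order.

    ``frame`` has one row per sample (true_maturity_age, true_state,
    evenness_factor, in_pulse); ``expected_proportions`` is the matching
    samples x OTUs matrix of expected community profiles.
    """

    frame: pd.DataFrame
    expected_proportions: np.ndarray


def _depth_lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[OtuTable, CohortMetadata, SimulationTruth]:
    """Generate one synthetic cohort: counts, metadata and ground truth.

    One sample per mouse per sampling day. Mouse ids are prefixed by group
    initial; cages hold up to two mice from the same group. The result is
    byte-identical for a fixed ``config.seed``.
    """
    lay = config.layout
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    mu, sigma = _depth_lognormal_params(config.depth_mean, config.depth_sd)

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    truth_rows: list[dict] = []
    expected_rows: list[np.ndarray] = []
    counts_rows: list[np.ndarray] = []

    for group in GROUPS:
        n_mice = config.n_mice_per_group.get(group, 0)
        for m in range(n_mice):
            mouse_id = f"{group[0].upper()}{m + 1}"
            cage_id = f"{group}_c{m // 2 + 1}"
            for t, day in enumerate(config.sampling_days, start=1):
                profile, exposure, state = expected_profile(day, group, config)
                depth = int(
                    max(config.min_depth, round(rng.lognormal(mu, sigma)))
                )
                counts = sample_counts(
                    profile, depth, config.overdispersion, rng
                )
                sid = f"{mouse_id}_tp{t:02d}"
                sample_ids.append(sid)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "mouse_id": mouse_id,
                        "cage_id": cage_id,
                        "group": group,
                        "day_of_life": int(day),
                        "timepoint_index": t,
                        "diet": (
                            "high_fat"
                            if day >= config.diet_switch_day
                            else "normal_chow"
                        ),
                    }
                )
                truth_rows.append(
                    {
                        "sample_id": sid,
                        "true_maturity_age": float(day - exposure.accumulated_lag),
                        "true_state": state,
                        "evenness_factor": exposure.evenness_factor,
                        "in_pulse": exposure.in_pulse,
                    }
                )
                expected_rows.append(profile)
                counts_rows.append(counts)

    table = OtuTable(
        sample_ids,
        list(lay.otu_ids),
        np.vstack(counts_rows) if counts_rows else np.zeros((0, config.n_otus), int),
        dict(lay.taxonomy),
    )
    meta = CohortMetadata(
        pd.DataFrame(meta_rows).set_index("sample_id"),
        diet_switch_day=config.diet_switch_day,
    )
    truth = SimulationTruth(
        frame=pd.DataFrame(truth_rows).set_index("sample_id"),
        expected_proportions=(
            np.vstack(expected_rows)
            if expected_rows
            else np.zeros((0, config.n_otus))
        ),
    )
    return table, meta, truth
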