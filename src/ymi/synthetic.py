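"""Synthetic fly cohorts: ground-truth generator for every analysis stage.

Each simulated fly carries three latent parameters:

* a stationary right-turn probability ``p`` drawn from a Beta
  distribution (or mixture) over flies — the population distribution of
  turn bias,
* a serial correlation ``ρ`` between consecutive turns, set via a
  target switchiness S* ≈ 1 − ρ, so S* = 1 recovers i.i.d. choices,
* a turn count ``n`` drawn from a negative binomial, reproducing the
  right-skewed, overdispersed activity distribution seen in real
  cohorts.

Turns are emitted by a two-state Markov chain with stationary marginal
``p`` and transitions P(R|R) = p + ρ(1−p), P(R|L) = p(1−ρ); its
expected alternation rate is 2p(1−p)(1−ρ), which is what makes mean
switchiness ≈ 1 − ρ.  The chain is the minimal model that decouples
bias from switchiness, mirroring their treatment as separate measures.

Cohorts come with full Table-style metadata (genotype × condition ×
sex × temperature design) and per-group variability multipliers, so
variance-heterogeneity analyses can be validated against injected
ground truth.  Measures in the emitted cohort table are always computed
from the emitted turn sequences by :mod:`ymi.measures` — never assigned
from the latent truth.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import measures as _measures
from .io import CohortTable, TABLE_COLUMNS
from .variability import add_levene_columns

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationSpec",
    "CohortResult",
    "rho_bounds",
    "sample_population",
    "simulate_turn_sequence",
    "simulate_turn_sequences",
    "generate_cohort",
    "sample_iid_measures",
]

_CHUNK_FLIES = 20_000  # sequence simulation batch size (memory bound)


@dataclass
class PopulationSpec:
    """Generative parameters for a synthetic cohort.

    The defaults emulate the study-scale conditions: bias distribution
    centred slightly left of 0.5 (mean 0.496, SD 0.15), per-fly target
    switchiness centred at 1 (SD 0.1), and overdispersed turn counts
    (negative binomial, mean 435 ≈ grand choices per fly, dispersion 2).

    ``group_effects`` maps a genotype (or (genotype, condition) pair)
    to per-measure SD multipliers, e.g. ``{"g01": {"bias": 2.0}}``
    doubles that genotype's bias SD; ``{"turns": 0.65}`` rescales the
    turn-count SD (hence CV) by re-solving the negative-binomial
    dispersion; ``{"switchiness": f}`` scales the S* spread.
    """

    n_flies_per_group: int = 100
    genotypes: tuple[str, ...] = tuple(f"line{i:02d}" for i in range(1, 11))
    conditions: tuple[str, ...] = ("normal",)
    sexes: tuple[str, ...] = ("female", "male")
    temperatures: tuple[float, ...] = (23.0,)
    bias_mean: float = 0.496
    bias_sd: float = 0.15
    bias_mixture: tuple[tuple[float, float, float], ...] | None = None
    switchiness_mean: float = 1.0
    switchiness_sd: float = 0.1
    turns_mean: float = 435.0
    turns_dispersion: float = 2.0
    group_effects: dict = field(default_factory=dict)
    emit_times: bool = False
    seed: int = 0

    def groups(self):
        return list(itertools.product(self.genotypes, self.conditions, self.sexes, self.temperatures))

    @property
    def n_flies(self) -> int:
        return self.n_flies_per_group * len(self.groups())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_effects"] = {str(k): v for k, v in self.group_effects.items()}
        return d


@dataclass
class CohortResult:
    cohort: CohortTable
    truth: pd.DataFrame
    sequences: list | None = None
    n_rho_clipped: int = 0


def rho_bounds(p):
    """Valid serial-correlation range for stationary bias p.

    Both transition probabilities must stay in [0, 1], giving
    ρ ∈ (−min(p, 1−p)/max(p, 1−p), 1).
    """
    p = np.asarray(p, dtype=float)
    lo = -np.minimum(p, 1 - p) / np.maximum(p, 1 - p)
    return lo, np.ones_like(p)


def _beta_params(mean: float, sd: float) -> tuple[float, float] | None:
    """Beta (α, β) for a given mean/SD; None signals a point mass (SD 0)."""
    if not 0 < mean < 1:
        raise ValueError("bias mean must lie in (0, 1)")
    if sd == 0:
        return None
    var = sd * sd
    if var >= mean * (1 - mean):
        raise ValueError("bias SD too large for a Beta distribution with this mean")
    kappa = mean * (1 - mean) / var - 1
    return mean * kappa, (1 - mean) * kappa


def _draw_bias(rng, mean: float, sd: float, size: int) -> np.ndarray:
    params = _beta_params(mean, sd)
    if params is None:
        return np.full(size, mean)
    return rng.beta(*params, size=size)


def _nbinom_params(mean: float, dispersion: float, sd_factor: float = 1.0) -> tuple[float, float]:
    """numpy (n, p) for a negative binomial with given mean/dispersion.

    ``sd_factor`` rescales the SD at fixed mean by re-solving the
    dispersion; the target variance must stay super-Poisson.
    """
    var = mean + mean * mean / dispersion
    if sd_factor != 1.0:
        var = sd_factor * sd_factor * var
        if var <= mean:
            raise ValueError("turn-count SD multiplier pushes variance below Poisson")
        dispersion = mean * mean / (var - mean)
    return dispersion, dispersion / (dispersion + mean)


def _group_factor(
    spec: PopulationSpec, genotype: str, condition: str, sex: str, which: str
) -> float:
    """Combined SD multiplier for one design cell.

    Matching ``group_effects`` keys multiply together: a genotype
    string, a ``(genotype, condition)`` pair, or the special keys
    ``("sex", <level>)`` / ``("expCond", <level>)`` for sex- or
    condition-wide effects.
    """
    factor = 1.0
    for key, eff in spec.group_effects.items():
        if (
            key == genotype
            or key == (genotype, condition)
            or key == ("sex", sex)
            or key == ("expCond", condition)
        ):
            factor *= float(eff.get(which, 1.0))
    return factor


def sample_population(spec: PopulationSpec, seed=None) -> tuple[pd.DataFrame, int]:
    """Draw per-fly latent parameters for the whole design.

    Returns (truth table, number of ρ values clipped into range).  The
    truth table has one row per fly: flyID, p_true, rho_true, n_true
    and the group labels.
    """
    groups = spec.groups()
    if not groups or spec.n_flies_per_group <= 0:
        raise ValueError("empty design")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    n_clipped = 0
    fly_id = 0
    for genotype, cond, sex, temp in groups:
        m = spec.n_flies_per_group
        bias_f = _group_factor(spec, genotype, cond, sex, "bias")
        turns_f = _group_factor(spec, genotype, cond, sex, "turns")
        switch_f = _group_factor(spec, genotype, cond, sex, "switchiness")
        if spec.bias_mixture is not None:
            weights = np.array([w for w, _, _ in spec.bias_mixture], dtype=float)
            weights = weights / weights.sum()
            comp = rng.choice(len(weights), size=m, p=weights)
            p_true = np.empty(m)
            for ci, (_, cm, csd) in enumerate(spec.bias_mixture):
                sel = comp == ci
                p_true[sel] = _draw_bias(rng, cm, csd * bias_f, int(sel.sum()))
        else:
            p_true = _draw_bias(rng, spec.bias_mean, spec.bias_sd * bias_f, m)
        # keep p strictly interior so the Markov chain is well defined
        p_true = np.clip(p_true, 1e-6, 1 - 1e-6)
        s_star = rng.normal(spec.switchiness_mean, spec.switchiness_sd * switch_f, size=m)
        rho = 1.0 - s_star
        lo, hi = rho_bounds(p_true)
        clipped = np.clip(rho, lo + 1e-9, 1.0 - 1e-9)
        n_clipped += int(np.sum(clipped != rho))
        nb_n, nb_p = _nbinom_params(spec.turns_mean, spec.turns_dispersion, turns_f)
        n_true = rng.negative_binomial(nb_n, nb_p, size=m)
        rows.append(
            pd.DataFrame(
                {
                    "flyID": np.arange(fly_id, fly_id + m),
                    "p_true": p_true,
                    "rho_true": clipped,
                    "n_true": n_true,
                    "genotype": genotype,
                    "expCond": cond,
                    "sex": sex,
                    "expTemp": temp,
                }
            )
        )
        fly_id += m
    if n_clipped:
        logger.info("sample_population: clipped rho for %d fly(ies)", n_clipped)
    return pd.concat(rows, ignore_index=True), n_clipped


def _simulate_batch(p, rho, n, rng) -> tuple[np.ndarray, np.ndarray]:
    """Padded 0/1 turn matrix for a batch of flies (rows) via the chain."""
    p = np.asarray(p, dtype=float)
    rho = np.asarray(rho, dtype=float)
    n = np.asarray(n, dtype=np.int64)
    lo, _ = rho_bounds(p)
    p_rr = p + rho * (1 - p)
    p_rl = p * (1 - rho)
    if np.any((p_rr < 0) | (p_rr > 1) | (p_rl < 0) | (p_rl > 1)):
        raise ValueError("transition probability outside [0, 1]; rho out of range for p")
    n_flies = p.size
    width = int(n.max()) if n_flies else 0
    turns = np.zeros((n_flies, width), dtype=np.uint8)
    if width == 0:
        return turns, n
    state = (rng.random(n_flies) < p).astype(np.uint8)
    turns[:, 0] = state
    for t in range(1, width):
        thresh = np.where(state == 1, p_rr, p_rl)
        state = (rng.random(n_flies) < thresh).astype(np.uint8)
        turns[:, t] = state
    return turns, n


def simulate_turn_sequence(p: float, rho: float, n: int, seed=None, rng=None):
    """Single fly's turn sequence from the two-state Markov chain."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    turns, _ = _simulate_batch([p], [rho], [n], rng)
    return _measures.TurnSequence(turns[0, :n])


def simulate_turn_sequences(p, rho, n, seed=None, rng=None) -> list:
    """Turn sequences for many flies at once (vectorized Markov chains).

    ``p``, ``rho`` and ``n`` are broadcast against each other; returns
    one :class:`~ymi.measures.TurnSequence` per fly.
    """
    p, rho, n = np.broadcast_arrays(
        np.asarray(p, dtype=float), np.asarray(rho, dtype=float),
        np.asarray(n, dtype=np.int64),
    )
    if rng is None:
        rng = np.random.default_rng(seed)
    turns, lengths = _simulate_batch(p.ravel(), rho.ravel(), n.ravel(), rng)
    return [
        _measures.TurnSequence(row[:m]) for row, m in zip(turns, lengths.astype(int))
    ]


def generate_cohort(spec: PopulationSpec, seed=None, keep_sequences: bool = True) -> CohortResult:
    """End-to-end synthetic cohort: sequences, measures table, truth.

    The cohort table's measures are computed from the emitted sequences
    (no analytic shortcut), its lev_* columns from genotype × condition
    group means, and the remaining metadata filled with fixed synthetic
    values.  Bit-reproducible from (spec, seed).
    """
    truth, n_clipped = sample_population(spec, seed=seed)
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed if seed is None else seed, 1])
    )
    measure_frames = []
    sequences: list | None = [] if keep_sequences else None
    for start in range(0, len(truth), _CHUNK_FLIES):
        chunk = truth.iloc[start : start + _CHUNK_FLIES]
        turns, lengths = _simulate_batch(
            chunk["p_true"].to_numpy(), chunk["rho_true"].to_numpy(),
            chunk["n_true"].to_numpy(), rng,
        )
        measure_frames.append(_measures._measures_from_padded(turns, lengths))
        if sequences is not None:
            for row, m in zip(turns, lengths):
                times = None
                if spec.emit_times and m > 0:
                    # placeholder timing: i.i.d. exponential gaps, non-physiological
                    times = np.cumsum(rng.exponential(2.0, size=int(m)))
                sequences.append(_measures.TurnSequence(row[: int(m)], times))
    meas = pd.concat(measure_frames, ignore_index=True)
    df = pd.DataFrame(
        {
            "flyID": truth["flyID"],
            "handedness": meas["turn_bias"],
            "numTurns": meas["num_turns"],
            "switchiness": meas["switchiness"],
            "genotype": truth["genotype"],
            "expCond": truth["expCond"],
            "expTemp": truth["expTemp"],
            "age": 3,
            "experimenterID": "synthetic",
            "trayID": "tray1",
            "boxID": "box1",
            "date": "2020-01-01",
            "arrayFormat": 120,
            "mazeNum": (truth["flyID"] % 120 + 1),
            "acquisition": "margo",
            "analysis": "ymi-synthetic",
            "sex": truth["sex"],
            "eyeColor": "+/+",
        }
    )
    df = add_levene_columns(df)
    df = df[[c for c in TABLE_COLUMNS if c in df.columns]]
    cohort = CohortTable(df=df, provenance=f"synthetic cohort, seed={spec.seed if seed is None else seed}")
    return CohortResult(cohort=cohort, truth=truth, sequences=sequences, n_rho_clipped=n_clipped)


def sample_iid_measures(spec: PopulationSpec, seed=None) -> CohortResult:
    """Exact-marginal measures for serially independent flies (ρ = 0).

    For a fly with i.i.d. turns, measured handedness is exactly
    Binomial(n, p)/n, so large cohorts can be sampled without emitting
    individual turns.  Only handedness and numTurns are filled
    (switchiness has no simple closed-form marginal and is left
    missing); requires switchiness_mean = 1 and zero spread, i.e. all
    ρ = 0.
    """
    if spec.switchiness_mean != 1.0 or spec.switchiness_sd != 0.0:
        raise ValueError("exact marginal sampling requires rho = 0 "
                         "(switchiness_mean=1, switchiness_sd=0)")
    truth, _ = sample_population(spec, seed=seed)
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed if seed is None else seed, 1])
    )
    n = truth["n_true"].to_numpy()
    r = rng.binomial(n, truth["p_true"].to_numpy())
    with np.errstate(invalid="ignore"):
        handedness = np.where(n > 0, r / np.maximum(n, 1), np.nan)
    df = pd.DataFrame(
        {
            "flyID": truth["flyID"],
            "handedness": handedness,
            "numTurns": n,
            "switchiness": np.nan,
            "genotype": truth["genotype"],
            "expCond": truth["expCond"],
            "expTemp": truth["expTemp"],
            "sex": truth["sex"],
        }
    )
    cohort = CohortTable(df=df, provenance="synthetic cohort (exact i.i.d. marginals)")
    return CohortResult(cohort=cohort, truth=truth, sequences=None)
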