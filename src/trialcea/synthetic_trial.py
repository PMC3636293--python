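"""Seeded generator for synthetic three-arm smoking-cessation trials.

The generator emulates the statistical structure of a pragmatic
three-arm cessation trial in Dutch general practice: unequal arm sizes
(multiple tailoring + counseling MTC, multiple tailoring only MT, usual
care UC), four measurement waves (baseline, 6 weeks, 6 months, 12
months), 3-month-recall resource-use questionnaires with right-skewed
costs, EQ-5D-3L health states sampled from a correlated ordinal model
and scored through the tariff (so the scoring path is exercised
end-to-end), prolonged-abstinence outcomes, and monotone loss to
follow-up concentrated among younger participants.

Two operations are exposed: :func:`generate_trial` produces a complete
long-format table, and :func:`apply_missingness` overlays monotone
dropout calibrated to a target marginal retention with a logistic age
gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from trialcea.costing import UnitPriceTable, index_price, CPI_DEFAULT
from trialcea.utility_qaly import ValueSet, EQ5D_DIMENSIONS

ARMS = ("MTC", "MT", "UC")

COST_CATEGORIES = (
    "gp",
    "specialist",
    "hospital",
    "alternative",
    "mental",
    "medication",
    "aids",
    "other",
)

EQ5D_COLUMNS = tuple(f"eq5d_{d}" for d in EQ5D_DIMENSIONS)

#: Mean euro spend per care category per 3-month recall window, by arm.
#: Calibrated to the baseline resource-use profile of a Dutch primary-care
#: smoking population; hospital costs dominate the variance.
DEFAULT_COST_MEANS = {
    "MTC": {
        "gp": 53.2, "specialist": 65.4, "hospital": 206.9, "alternative": 5.1,
        "mental": 30.3, "medication": 26.7, "aids": 1.7, "other": 26.0,
    },
    "MT": {
        "gp": 61.0, "specialist": 78.6, "hospital": 50.9, "alternative": 9.4,
        "mental": 24.3, "medication": 36.4, "aids": 3.4, "other": 19.2,
    },
    "UC": {
        "gp": 49.7, "specialist": 87.6, "hospital": 47.9, "alternative": 4.9,
        "mental": 38.2, "medication": 13.6, "aids": 1.9, "other": 12.5,
    },
}

# Marginal level probabilities (no / some / many complaints) per EQ-5D
# dimension for a middle-aged smoking population, chosen together with the
# copula correlation so that scored utilities come out near mean 0.8,
# SD 0.2 under the Dutch tariff.
_EQ5D_MARGINALS = {
    "mo": (0.71, 0.275, 0.015),
    "sc": (0.925, 0.0675, 0.0075),
    "ua": (0.71, 0.275, 0.015),
    "pd": (0.435, 0.540, 0.025),
    "ad": (0.61, 0.365, 0.025),
}
_EQ5D_COPULA_RHO = 0.45  # common latent correlation across dimensions
_EQ5D_WAVE_WEIGHT = 0.6  # share of latent variance persistent across waves


class ConfigurationError(ValueError):
    """Raised when a :class:`TrialConfig` field is out of range."""


@dataclass
class TrialConfig:
    """Parameters of the synthetic trial.

    Attributes
    ----------
    arm_sizes:
        Participants per arm in order (MTC, MT, UC).
    abstinence_probs:
        Per-arm probability of prolonged abstinence at 12 months in the
        complete (pre-dropout) data.
    utility_mean, utility_sd:
        Target location/scale of baseline EQ-5D utilities.  The ordinal
        item model is anchored at (0.8, 0.2); other means are reached by
        a latent location shift, the SD is not independently tunable.
    cost_means:
        Mean euro spend per category per arm per 3-month recall window
        (index-year euros).
    cost_dispersion:
        Negative-binomial overdispersion alpha (variance = m + alpha*m^2
        on the count scale); 0 gives Poisson counts.
    dropout_rate:
        Target marginal probability of being lost to follow-up by 12
        months.
    dropout_age_coefficient:
        Log-odds of dropout per year of age (negative: younger
        participants drop out more).
    wave_times:
        Measurement times in years from baseline.
    seed:
        Root seed; all generator randomness derives from it.
    """

    arm_sizes: tuple[int, int, int] = (163, 132, 119)
    abstinence_probs: tuple[float, float, float] = (0.086, 0.152, 0.101)
    utility_mean: float = 0.8
    utility_sd: float = 0.2
    cost_means: dict = field(default_factory=lambda: {
        a: dict(DEFAULT_COST_MEANS[a]) for a in ARMS
    })
    cost_dispersion: float = 4.0
    dropout_rate: float = 0.442
    dropout_age_coefficient: float = -0.04
    wave_times: tuple[float, ...] = (0.0, 0.115, 0.5, 1.0)
    recall_years: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.arm_sizes) != 3 or any(int(n) <= 0 for n in self.arm_sizes):
            raise ConfigurationError("arm_sizes must be three positive integers")
        if any(not (0.0 <= p <= 1.0) for p in self.abstinence_probs):
            raise ConfigurationError("abstinence_probs must lie in [0, 1]")
        if not (0.0 <= self.utility_mean <= 1.0):
            raise ConfigurationError("utility_mean must lie in [0, 1]")
        if self.utility_sd < 0:
            raise ConfigurationError("utility_sd must be non-negative")
        if self.cost_dispersion < 0:
            raise ConfigurationError("cost_dispersion must be non-negative")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ConfigurationError("dropout_rate must lie in [0, 1]")
        wt = tuple(self.wave_times)
        if len(wt) < 2 or wt[0] != 0.0 or any(b <= a for a, b in zip(wt, wt[1:])):
            raise ConfigurationError(
                "wave_times must be strictly increasing and start at 0"
            )
        for arm in ARMS:
            if arm not in self.cost_means:
                raise ConfigurationError(f"cost_means missing arm {arm!r}")
            for cat, m in self.cost_means[arm].items():
                if m < 0:
                    raise ConfigurationError(f"negative cost mean for {arm}/{cat}")

    @property
    def n_waves(self) -> int:
        return len(self.wave_times)

    @property
    def n_total(self) -> int:
        return int(sum(self.arm_sizes))


def _rng(config: TrialConfig, stream: str) -> np.random.Generator:
    """Named substream of the config's root seed."""
    streams = {"trial": 0, "missingness": 1}
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), streams[stream]])
    )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               alpha: float) -> np.ndarray:
    """Negative-binomial counts with var = m + alpha*m^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0.0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + np.maximum(mean, 1e-12))
    out = rng.negative_binomial(r, p)
    out[mean == 0.0] = 0
    return out


def _eq5d_thresholds() -> dict[str, tuple[float, float]]:
    return {
        d: (norm.ppf(p1), norm.ppf(p1 + p2))
        for d, (p1, p2, _p3) in _EQ5D_MARGINALS.items()
    }


def _latent_shift_for_mean(target_mean: float, value_set: ValueSet) -> float:
    """Location shift of the latent scale matching a target utility mean.

    The ordinal model is anchored at mean 0.8; other targets are reached
    by shifting every latent variable by a constant found by bisection on
    a fixed-seed Monte-Carlo estimate of the scored mean.
    """
    if abs(target_mean - 0.8) < 5e-3:
        return 0.0
    thr = _eq5d_thresholds()

    def scored_mean(shift: float) -> float:
        rng = np.random.default_rng(20_11)
        n = 20_000
        z = _correlated_normals(rng, n, len(EQ5D_DIMENSIONS))
        levels = {
            d: _levels_from_latent(z[:, j] + shift, thr[d])
            for j, d in enumerate(EQ5D_DIMENSIONS)
        }
        u = value_set.utilities(np.column_stack([levels[d] for d in EQ5D_DIMENSIONS]))
        return float(u.mean())

    lo, hi = -3.0, 3.0
    return brentq(lambda s: scored_mean(s) - target_mean, lo, hi, xtol=1e-3)


def _correlated_normals(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    """Equicorrelated standard normals via a one-factor construction."""
    rho = _EQ5D_COPULA_RHO
    common = rng.standard_normal((n, 1))
    idio = rng.standard_normal((n, d))
    return np.sqrt(rho) * common + np.sqrt(1.0 - rho) * idio


def _levels_from_latent(z: np.ndarray, thr: tuple[float, float]) -> np.ndarray:
    return 1 + (z > thr[0]).astype(int) + (z > thr[1]).astype(int)


def generate_trial(config: TrialConfig,
                   prices: UnitPriceTable | None = None) -> pd.DataFrame:
    """Generate a complete long-format participant table.

    One row per participant per wave.  Costs arise as negative-binomial
    resource counts per category multiplied by (indexed) unit prices, so
    their distribution is right-skewed with arm-specific means; EQ-5D
    items come from a Gaussian-copula ordinal model with a persistent
    person effect across waves; prolonged abstinence is Bernoulli per
    arm.  Deterministic given ``config.seed``.
    """
    if prices is None:
        prices = UnitPriceTable.default()
    rng = _rng(config, "trial")
    n = config.n_total
    n_waves = config.n_waves
    value_set = ValueSet.dutch()

    arm = np.repeat(ARMS, config.arm_sizes)
    pid = np.arange(1, n + 1)

    age = np.clip(rng.normal(48.0, 12.0, n), 18, 85).round(0)
    sex = rng.choice(["male", "female"], size=n, p=(0.40, 0.60))
    education = rng.choice(["high", "medium", "low"], size=n, p=(0.22, 0.45, 0.33))

    # per-wave resource counts, category by category
    indexed = {
        c: index_price(prices[c].unit_price,
                       CPI_DEFAULT[prices[c].price_year],
                       CPI_DEFAULT[prices.index_year])
        for c in COST_CATEGORIES
    }
    counts = {}
    for cat in COST_CATEGORIES:
        mean_count = np.array(
            [config.cost_means[a][cat] / indexed[cat] for a in arm]
        )
        counts[cat] = np.column_stack([
            _nb_counts(rng, mean_count, config.cost_dispersion)
            for _ in range(n_waves)
        ])

    # prolonged abstinence at 12 months, Bernoulli per arm
    p_abst = np.select([arm == a for a in ARMS], config.abstinence_probs)
    abstainer = rng.random(n) < p_abst
    status = np.ones((n, n_waves), dtype=int)
    # transient early quitting among eventual non-abstainers, and an early
    # quit date for most prolonged abstainers
    if n_waves >= 2:
        early = np.where(abstainer, 0.7, 0.10)
        status[:, 1] = np.where(rng.random(n) < early, 2, 1)
    for w in range(2, n_waves):
        relapse_free = abstainer if w == n_waves - 1 else (
            abstainer | (rng.random(n) < 0.05)
        )
        status[:, w] = np.where(relapse_free, 2, 1)

    # FTND addiction score: stable with slight decline; abstainers lower
    ftnd0 = np.clip(np.rint(rng.normal(5.4, 2.1, n)), 0, 10)
    ftnd = np.column_stack([ftnd0] + [
        np.clip(
            ftnd0 + np.rint(rng.normal(-0.4 * w, 1.2, n)) - 2 * (status[:, w] == 2),
            0, 10,
        )
        for w in range(1, n_waves)
    ])

    # EQ-5D items: one-factor copula per wave with a persistent person effect
    thr = _eq5d_thresholds()
    shift = _latent_shift_for_mean(config.utility_mean, value_set)
    w_person = _EQ5D_WAVE_WEIGHT
    person = _correlated_normals(rng, n, len(EQ5D_DIMENSIONS))
    eq5d = {}
    for w in range(n_waves):
        fresh = _correlated_normals(rng, n, len(EQ5D_DIMENSIONS))
        z = np.sqrt(w_person) * person + np.sqrt(1 - w_person) * fresh + shift
        # mild improvement for currently-abstinent participants
        z = z - 0.15 * (status[:, w] == 2)[:, None]
        for j, d in enumerate(EQ5D_DIMENSIONS):
            eq5d[(d, w)] = _levels_from_latent(z[:, j], thr[d])

    rows = []
    for w in range(n_waves):
        frame = pd.DataFrame({
            "id": pid,
            "arm": arm,
            "age": age,
            "sex": sex,
            "education": education,
            "wave": w,
            "wave_time": config.wave_times[w],
        })
        for cat in COST_CATEGORIES:
            frame[cat] = counts[cat][:, w]
        for d in EQ5D_DIMENSIONS:
            frame[f"eq5d_{d}"] = eq5d[(d, w)]
        frame["smoking_status"] = status[:, w]
        frame["ftnd"] = ftnd[:, w]
        rows.append(frame)
    table = pd.concat(rows, ignore_index=True)
    table = table.sort_values(["id", "wave"], kind="stable").reset_index(drop=True)
    return table


_MASKABLE = list(COST_CATEGORIES) + list(EQ5D_COLUMNS) + ["smoking_status", "ftnd"]

#: Probability that a dropout first goes missing at wave 1, 2, 3 ...
#: (per-wave retention is not identified by a single 12-month figure).
DROPOUT_WAVE_PROBS = (0.4, 0.3, 0.3)


def apply_missingness(table: pd.DataFrame, config: TrialConfig) -> pd.DataFrame:
    """Overlay monotone dropout on a complete table.

    Each participant drops out with probability given by a logistic model
    in age whose intercept is solved so that the realized-age marginal
    dropout probability equals ``config.dropout_rate`` exactly; the slope
    is ``dropout_age_coefficient`` (negative by default, so completers
    are older on average).  A dropout's first missing wave is drawn from
    :data:`DROPOUT_WAVE_PROBS`; all measurements from that wave on are
    set to missing.  Baseline is never missing.
    """
    if not (0.0 <= config.dropout_rate <= 1.0):
        raise ConfigurationError("dropout_rate must lie in [0, 1]")
    out = table.copy()
    if config.dropout_rate == 0.0:
        return out
    rng = _rng(config, "missingness")

    base = table[table["wave"] == 0]
    ages = base["age"].to_numpy(dtype=float)
    ids = base["id"].to_numpy()
    beta = config.dropout_age_coefficient

    def marginal(b0: float) -> float:
        return float(expit(b0 + beta * (ages - ages.mean())).mean())

    if config.dropout_rate >= 1.0:
        p_drop = np.ones_like(ages)
    else:
        b0 = brentq(lambda b: marginal(b) - config.dropout_rate, -30.0, 30.0)
        p_drop = expit(b0 + beta * (ages - ages.mean()))

    drops = rng.random(len(ids)) < p_drop
    n_waves = config.n_waves
    wave_probs = np.asarray(DROPOUT_WAVE_PROBS[: n_waves - 1], dtype=float)
    wave_probs = wave_probs / wave_probs.sum()
    first_missing = rng.choice(np.arange(1, n_waves), size=len(ids), p=wave_probs)

    drop_ids = ids[drops]
    fm = pd.Series(first_missing[drops], index=drop_ids)
    wave = out["wave"].to_numpy()
    mapped = out["id"].map(fm)  # NaN for completers
    mask = mapped.notna().to_numpy() & (wave >= mapped.fillna(n_waves).to_numpy())
    cols = [c for c in _MASKABLE if c in out.columns]
    out[cols] = out[cols].astype(float)
    out.loc[mask, cols] = np.nan
    return out


def write_participant_csv(table: pd.DataFrame, path) -> None:
    """Write the canonical long-format participant CSV."""
    table.to_csv(path, index=False)


def read_participant_csv(path) -> pd.DataFrame:
    """Read the canonical long-format participant CSV."""
    return pd.read_csv(path)
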