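"""EQ-5D-3L utility scoring and area-under-the-curve QALYs.

EQ-5D-3L describes health by five dimensions (mobility, self-care,
usual activities, pain/discomfort, anxiety/depression), each at three
levels (1 = no complaints, 2 = some, 3 = many).  A national value set
("tariff") maps each of the 243 states to a utility anchored at 1 for
full health (state 11111).  Utilities observed at the measurement waves
are accumulated into QALYs as the area under the utility-time curve
over the follow-up year.

All operations are tariff-agnostic; the Dutch tariff is shipped as a
data file and loaded with :meth:`ValueSet.dutch`.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

EQ5D_DIMENSIONS = ("mo", "sc", "ua", "pd", "ad")
N_STATES = 3 ** 5


class HorizonWarning(UserWarning):
    """The utility profile does not span exactly one year."""


def _validate_state(levels) -> tuple[int, ...]:
    levels = tuple(int(v) for v in levels)
    if len(levels) != 5:
        raise ValueError("an EQ-5D-3L state has exactly 5 dimension levels")
    if any(v not in (1, 2, 3) for v in levels):
        raise ValueError(f"EQ-5D-3L levels must be in {{1,2,3}}; got {levels}")
    return levels


def state_code(levels) -> str:
    """5-digit string code of a state, e.g. (1,1,2,1,1) -> '11211'."""
    return "".join(str(v) for v in _validate_state(levels))


def all_states():
    """All 243 states in lexicographic order."""
    for mo in (1, 2, 3):
        for sc in (1, 2, 3):
            for ua in (1, 2, 3):
                for pd_ in (1, 2, 3):
                    for ad in (1, 2, 3):
                        yield (mo, sc, ua, pd_, ad)


@dataclass
class ValueSet:
    """A complete EQ-5D-3L tariff: every 5-digit state -> utility <= 1."""

    name: str
    mapping: dict[str, float]

    def __post_init__(self):
        missing = [state_code(s) for s in all_states() if state_code(s) not in self.mapping]
        if missing:
            raise ValueError(
                f"value set {self.name!r} undefined for {len(missing)} states "
                f"(first: {missing[0]})"
            )
        if abs(self.mapping["11111"] - 1.0) > 1e-9:
            raise ValueError("state 11111 must map to utility 1.0")
        if any(u > 1.0 + 1e-9 for u in self.mapping.values()):
            raise ValueError("utilities must not exceed 1.0")

    def __getitem__(self, code: str) -> float:
        return self.mapping[code]

    def utilities(self, levels: np.ndarray) -> np.ndarray:
        """Vectorized scoring of an (n, 5) integer level array."""
        levels = np.asarray(levels, dtype=int)
        if levels.ndim != 2 or levels.shape[1] != 5:
            raise ValueError("levels must be an (n, 5) array")
        if ((levels < 1) | (levels > 3)).any():
            raise ValueError("EQ-5D-3L levels must be in {1,2,3}")
        idx = np.zeros(len(levels), dtype=int)
        for j in range(5):
            idx = idx * 3 + (levels[:, j] - 1)
        lut = np.array([self.mapping[state_code(s)] for s in all_states()])
        return lut[idx]

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "ValueSet":
        df = pd.read_csv(path, dtype={"state": str})
        if not {"state", "utility"}.issubset(df.columns):
            raise ValueError("value-set CSV needs columns: state, utility")
        mapping = dict(zip(df["state"], df["utility"].astype(float)))
        return cls(name=name or str(path), mapping=mapping)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"state": list(self.mapping), "utility": list(self.mapping.values())}
        ).to_csv(path, index=False)

    @classmethod
    def dutch(cls) -> "ValueSet":
        """The Dutch EQ-5D-3L tariff (packaged data file)."""
        ref = importlib.resources.files("trialcea.data") / "nl_eq5d3l_tariff.csv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path, name="NL-3L")


def state_to_utility(state, value_set: ValueSet) -> float:
    """Utility of one EQ-5D-3L state under a value set."""
    return float(value_set[state_code(state)])


@dataclass
class UtilityProfile:
    """Utilities observed at strictly increasing times (years)."""

    wave_times: tuple[float, ...]
    utilities: tuple[float, ...]

    def __post_init__(self):
        if len(self.wave_times) != len(self.utilities):
            raise ValueError("wave_times and utilities must have equal length")
        if len(self.wave_times) < 2:
            raise ValueError("a utility profile needs at least two waves")
        t = self.wave_times
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("wave_times must be strictly increasing")


def qaly_auc(profile: UtilityProfile, method: str = "trapezoid") -> float:
    """QALYs accumulated over the profile's horizon.

    The area under the utility-time curve: with ``trapezoid`` utilities
    are interpolated linearly between waves; with ``rectangle`` each
    inter-wave interval is valued at its starting utility (duration of
    the health state times its quality weight).  A horizon different
    from one year triggers :class:`HorizonWarning` but is still
    integrated as given.
    """
    t = np.asarray(profile.wave_times, dtype=float)
    u = np.asarray(profile.utilities, dtype=float)
    span = t[-1] - t[0]
    if abs(span - 1.0) > 1e-9:
        warnings.warn(
            f"utility profile spans {span:g} years, not 1", HorizonWarning
        )
    if method == "trapezoid":
        return float(np.trapezoid(u, t))
    if method == "rectangle":
        return float(np.sum(u[:-1] * np.diff(t)))
    raise ValueError(f"unknown AUC method {method!r}")


def qaly_table(table: pd.DataFrame, value_set: ValueSet,
               method: str = "trapezoid") -> pd.Series:
    """Per-participant QALYs from a complete long-format table.

    Participants with any missing EQ-5D item (non-imputable records) get
    NaN.  Index is participant id.
    """
    cols = [f"eq5d_{d}" for d in EQ5D_DIMENSIONS]
    tab = table.sort_values(["id", "wave_time"])
    levels = tab[cols].to_numpy(dtype=float)
    ok = ~np.isnan(levels).any(axis=1)
    util = np.full(len(tab), np.nan)
    if ok.any():
        util[ok] = value_set.utilities(levels[ok].astype(int))
    tab = tab.assign(_u=util)

    def per_participant(g: pd.DataFrame) -> float:
        if g["_u"].isna().any():
            return np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", HorizonWarning)
            return qaly_auc(
                UtilityProfile(tuple(g["wave_time"]), tuple(g["_u"])),
                method=method,
            )

    return tab.groupby("id", sort=True).apply(per_participant, include_groups=False)
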