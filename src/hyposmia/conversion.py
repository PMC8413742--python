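"""Monotone conversion between the 40-item UPSIT and 16-item Sniffin' Sticks scales.

The two olfactory identification tests score on different ranges (0-40 vs
0-16).  Mixed cohorts are put on a common footing by a monotone lookup table
mapping each integer UPSIT score to a Sniffin' Sticks (SS) equivalent.  The
published mapping comes from an item-response-theory equating study; here the
table is a pluggable CSV asset, with a documented piecewise-linear default
(0 -> 0, 40 -> 16, steps of 0.5) shipped for testing and simulation.

Classification rules stated in UPSIT units are applied to SS-tested subjects
by converting the *cut-off*, not the score: the converted threshold is chosen
so that the classified set is exactly the image of the UPSIT-classified set
under the monotone mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

UPSIT_MAX = 40
SS_MAX = 16

_DEFAULT_ASSET = "upsit_to_ss_default.csv"


@dataclass(frozen=True)
class ConversionTable:
    """Ordered pairs (UPSIT integer 0-40 -> SS equivalent 0-16).

    Invariants enforced at construction: defined on every integer 0..40,
    non-decreasing, endpoints anchored at ss(0)=0 and ss(40)=16.
    """

    ss_values: np.ndarray  # index = UPSIT score
    provenance: str = field(default="unspecified")

    def __post_init__(self) -> None:
        vals = np.asarray(self.ss_values, dtype=float)
        if vals.shape != (UPSIT_MAX + 1,):
            raise ValueError(
                f"conversion table must define all integers 0..{UPSIT_MAX} "
                f"(got {vals.shape[0]} entries)"
            )
        if np.any(np.diff(vals) < 0):
            raise ValueError("conversion table must be non-decreasing")
        if vals[0] != 0.0 or vals[-1] != float(SS_MAX):
            raise ValueError("conversion table endpoints must be ss(0)=0, ss(40)=16")
        object.__setattr__(self, "ss_values", vals)

    def to_ss(self, upsit_score):
        """SS equivalent of integer UPSIT score(s); raises outside 0..40."""
        s = np.asarray(upsit_score)
        if np.any((s < 0) | (s > UPSIT_MAX)):
            raise ValueError(f"UPSIT score outside table domain 0..{UPSIT_MAX}")
        out = self.ss_values[s.astype(int)]
        return float(out) if np.isscalar(upsit_score) else out

    def to_upsit(self, ss_value):
        """Lower-preimage back-conversion: minimal UPSIT score u with ss(u) >= value."""
        v = np.atleast_1d(np.asarray(ss_value, dtype=float))
        if np.any((v < 0) | (v > SS_MAX)):
            raise ValueError(f"SS value outside 0..{SS_MAX}")
        out = np.searchsorted(self.ss_values, v, side="left")
        return int(out[0]) if np.isscalar(ss_value) else out.astype(int)

    def nearest_upsit(self, ss_value):
        """UPSIT score whose SS equivalent is closest to ``ss_value`` (ties -> lower)."""
        v = np.atleast_1d(np.asarray(ss_value, dtype=float))
        d = np.abs(self.ss_values[None, :] - v[:, None])
        out = np.argmin(d, axis=1)
        return int(out[0]) if np.isscalar(ss_value) else out.astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"upsit_score": np.arange(UPSIT_MAX + 1), "ss_equivalent": self.ss_values}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str | None = None) -> "ConversionTable":
        df = pd.read_csv(path)
        for col in ("upsit_score", "ss_equivalent"):
            if col not in df.columns:
                raise ValueError(f"conversion table CSV missing column '{col}'")
        df = df.sort_values("upsit_score")
        if not np.array_equal(df["upsit_score"].to_numpy(), np.arange(UPSIT_MAX + 1)):
            raise ValueError("conversion table CSV must list every integer 0..40 once")
        return cls(
            df["ss_equivalent"].to_numpy(float),
            provenance=provenance or str(Path(path).name),
        )

    @classmethod
    def default(cls) -> "ConversionTable":
        """The shipped piecewise-linear table (0.4 SS per UPSIT point, 0.5 rounding)."""
        with resources.as_file(
            resources.files("hyposmia").joinpath("data", _DEFAULT_ASSET)
        ) as p:
            return cls.from_csv(p, provenance="default-piecewise-linear")


def default_table_values() -> np.ndarray:
    """SS equivalents of the default table: round(0.4*u to the nearest 0.5)."""
    u = np.arange(UPSIT_MAX + 1)
    return np.round(0.4 * u * 2.0) / 2.0


def convert_cutoff(upsit_cutoff: int, table: ConversionTable, direction: str = "at_or_below") -> float:
    """SS-scale threshold equivalent to a UPSIT-scale cut-off.

    ``at_or_below c`` (score <= c) converts to ``score_ss <= ss(c)``;
    ``below c`` (score < c, i.e. <= c-1) converts to ``score_ss <= ss(c-1)``.
    The returned value is the SS threshold; for ``below 0`` (nobody
    classified) it is -1.0, which no valid SS score satisfies.
    """
    if not 0 <= upsit_cutoff <= UPSIT_MAX:
        raise ValueError(f"cutoff {upsit_cutoff} outside 0..{UPSIT_MAX}")
    if direction == "at_or_below":
        return float(table.to_ss(upsit_cutoff))
    if direction == "below":
        return float(table.to_ss(upsit_cutoff - 1)) if upsit_cutoff >= 1 else -1.0
    raise ValueError(f"unknown direction {direction!r}")


def convert_scores(cohort, table: ConversionTable | None = None):
    """Return a copy of the cohort with ``score_ss`` populated for every subject.

    SS-tested subjects keep their raw score (identity); UPSIT-tested subjects
    get the table lookup and retain their native score in ``score_upsit``.
    """
    from .cohort import Cohort  # local import to avoid a cycle

    table = table or ConversionTable.default()
    df = cohort.df.copy()
    is_ss = df["test_kind"] == "SS16"
    df["score_ss"] = np.where(
        is_ss,
        df["raw_score"].astype(float),
        table.to_ss(np.where(is_ss, 0, df["raw_score"]).astype(int)),
    )
    df["score_upsit"] = np.where(is_ss, np.nan, df["raw_score"].astype(float))
    return Cohort(df)
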