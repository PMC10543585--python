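"""Species-level trait table assembly and engineering.

The analyses work on a species x variables table holding natural-log
volumes of amygdala regions — the amygdaloid complex (AC), the
basolateral nucleus (BLA) and its lateral (L), basal (B) and accessory
basal (AB) constituents — together with seven allomaternal-care
component scores, their compound sums, and three binary regimes:

* ``cooperative_breeder`` — obtained by two-cluster discretization of the
  compound allocare score,
* ``domesticated`` — an input flag,
* ``elicit_care`` — the elementwise OR of the two.

Individual-level records (one row per measured animal, possibly with
separate left/right hemisphere columns) are aggregated to species means
*before* the log transform: hemispheres are averaged within an
individual, individuals are averaged within a species, and the species
mean volume is then log-transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("phyloconverge")

from .tree import normalize_label

VOLUME_COLS = ["AC", "BLA", "L", "B", "AB"]
ALLOCARE_COMPONENTS = [
    "male_provisioning",
    "other_provisioning",
    "male_carrying",
    "other_carrying",
    "allonursing",
    "male_protection",
    "communal_work",
]
CARRYING_COMPONENTS = ["male_carrying", "other_carrying"]
BINARY_COLS = ["cooperative_breeder", "domesticated", "elicit_care"]

__all__ = [
    "TraitTable",
    "DiscretizationResult",
    "load_traits",
    "compound_allocare",
    "kmeans_discretize_1d",
    "make_elicit_care",
    "VOLUME_COLS",
    "ALLOCARE_COMPONENTS",
]


@dataclass
class DiscretizationResult:
    """Two-cluster split of a 1-D score: threshold, labels, within-SS."""

    break_point: float
    labels: pd.Series
    within_cluster_ss: float


@dataclass
class TraitTable:
    """Species-level trait table (volumes stored on the natural-log scale)."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = [normalize_label(s) for s in self.data.index]
        self.data.index.name = "species"

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def column(self, name: str) -> pd.Series:
        return self.data[name]

    def subset(self, species) -> "TraitTable":
        keep = [normalize_label(s) for s in species]
        missing = sorted(set(keep) - set(self.data.index))
        if missing:
            raise KeyError(f"species not in trait table: {missing}")
        return TraitTable(self.data.loc[keep])

    def validate(self, strict: bool = False, rtol: float = 0.05) -> list[str]:
        """Check anatomical and construction invariants.

        Hard violations (non-binary regimes, inconsistent compound sums,
        elicit_care not the OR of its parts) always raise.  Anatomical
        checks — BLA <= AC and L + B + AB ~ BLA on the volume scale —
        raise only when ``strict``; otherwise they are logged, since
        literature-compiled volumes need not nest exactly.
        """
        df = self.data
        problems: list[str] = []
        for col in BINARY_COLS:
            if col in df and not df[col].isin([0, 1]).all():
                raise ValueError(f"{col} must be 0/1")
        if set(ALLOCARE_COMPONENTS) <= set(df.columns):
            comp = df[ALLOCARE_COMPONENTS]
            if (comp.to_numpy() < 0).any():
                raise ValueError("allocare components must be nonnegative")
            if "allocare_sum" in df and not np.allclose(
                df["allocare_sum"], comp.sum(axis=1), atol=1e-9
            ):
                raise ValueError("allocare_sum != sum of the 7 components")
            if "allocare_sum_nocarry" in df and not np.allclose(
                df["allocare_sum_nocarry"],
                comp.drop(columns=CARRYING_COMPONENTS).sum(axis=1),
                atol=1e-9,
            ):
                raise ValueError("allocare_sum_nocarry != sum without carrying")
        if set(BINARY_COLS) <= set(df.columns):
            expected = make_elicit_care(df["cooperative_breeder"], df["domesticated"])
            if not (df["elicit_care"].to_numpy() == expected.to_numpy()).all():
                raise ValueError("elicit_care is not cooperative_breeder OR domesticated")
        if set(VOLUME_COLS) <= set(df.columns):
            vol = np.exp(df[VOLUME_COLS])
            if (vol["BLA"] > vol["AC"] * (1 + rtol)).any():
                problems.append("BLA volume exceeds AC volume for some species")
            resid = (vol[["L", "B", "AB"]].sum(axis=1) - vol["BLA"]).abs() / vol["BLA"]
            if (resid > rtol).any():
                problems.append("L + B + AB deviates from BLA beyond tolerance")
        for msg in problems:
            if strict:
                raise ValueError(msg)
            logger.warning("trait table: %s", msg)
        return problems

    def to_csv(self, path) -> None:
        self.data.to_csv(path)

    def to_input_csv(self, path) -> None:
        """Write a CSV in the format :func:`load_traits` reads.

        Volumes are back-transformed to the cm^3 scale; derived columns
        (compound sums and the discretized/OR'd regimes) are dropped so
        the loader and :func:`engineer_traits` can rebuild them.
        """
        df = self.data.copy()
        df[[c for c in VOLUME_COLS if c in df]] = np.exp(
            df[[c for c in VOLUME_COLS if c in df]]
        )
        drop = ["allocare_sum", "allocare_sum_nocarry", "cooperative_breeder",
                "elicit_care"]
        df = df.drop(columns=[c for c in drop if c in df])
        df.to_csv(path)


# ---------------------------------------------------------------------------
# Loading / aggregation


def _merge_hemispheres(df: pd.DataFrame, volume_cols) -> pd.DataFrame:
    """Average ``X_left``/``X_right`` pairs into ``X`` where present."""
    df = df.copy()
    for col in volume_cols:
        lo, hi = f"{col}_left", f"{col}_right"
        if lo in df.columns and hi in df.columns:
            both = df[[lo, hi]].mean(axis=1)
            df[col] = df[col].fillna(both) if col in df.columns else both
            df = df.drop(columns=[lo, hi])
    return df


def load_traits(
    source,
    species_col: str = "species",
    column_map: dict[str, str] | None = None,
) -> TraitTable:
    """Build a species-level :class:`TraitTable` from a CSV (or DataFrame).

    One row per individual (or per species, if already aggregated).
    Hemisphere columns ``<vol>_left`` / ``<vol>_right`` are averaged per
    individual; individuals are averaged per species; species mean
    volumes are then natural-log transformed.  Allocare components and
    binary flags are species-level attributes and must be constant
    within a species (the first value is taken; disagreement raises).

    Parameters
    ----------
    source
        Path to a CSV with a header row, or an equivalent DataFrame.
    column_map
        Optional renaming of input columns to canonical names, e.g.
        ``{"Lateral": "L"}``.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    if column_map:
        df = df.rename(columns=column_map)
    if species_col not in df.columns:
        raise ValueError(f"required column {species_col!r} missing from trait CSV")
    df[species_col] = df[species_col].map(normalize_label)
    df = _merge_hemispheres(df, VOLUME_COLS)
    vol_cols = [c for c in VOLUME_COLS if c in df.columns]
    missing = sorted(set(VOLUME_COLS) - set(vol_cols))
    if missing:
        raise ValueError(f"required volume columns missing: {missing}")

    grouped = df.groupby(species_col, sort=True)
    means = grouped[vol_cols].mean()
    if (means.to_numpy() <= 0).any() or means.isna().to_numpy().any():
        bad = means.index[(means <= 0).any(axis=1) | means.isna().any(axis=1)]
        raise ValueError(f"nonpositive or missing mean volume for {list(bad)}")
    out = np.log(means)

    passthrough = [
        c
        for c in ALLOCARE_COMPONENTS + BINARY_COLS + ["allocare_sum", "allocare_sum_nocarry"]
        if c in df.columns
    ]
    for col in passthrough:
        per_species = grouped[col].agg(["min", "max", "first"])
        if not np.allclose(per_species["min"], per_species["max"], equal_nan=True):
            raise ValueError(f"species-level column {col!r} varies within a species")
        out[col] = per_species["first"]

    table = TraitTable(out)
    table.validate(strict=False)
    return table


# ---------------------------------------------------------------------------
# Allocare compounding and regimes


def compound_allocare(components, no_carry: bool = False):
    """Sum the seven allomaternal-care component scores.

    ``components`` is a DataFrame (or mapping) with the seven canonical
    columns.  With ``no_carry=True`` the two infant-carrying components
    are omitted, giving the variant used for species that never carry
    infants at all.
    """
    comp = pd.DataFrame(components)[ALLOCARE_COMPONENTS]
    if (comp.to_numpy() < 0).any():
        raise ValueError("allocare components must be nonnegative")
    cols = [c for c in ALLOCARE_COMPONENTS if not (no_carry and c in CARRYING_COMPONENTS)]
    return comp[cols].sum(axis=1)


def kmeans_discretize_1d(values, k: int = 2) -> DiscretizationResult:
    """Globally optimal two-cluster split of 1-D scores.

    In one dimension the optimal k-means partition respects the sort
    order, so the minimum within-cluster sum of squares is found by an
    exhaustive scan over the n - 1 sorted split points — deterministic,
    with no dependence on starting centroids.  The break point is the
    midpoint between the largest low-cluster and smallest high-cluster
    values, matching interval-style reporting such as "0 to 2.64 /
    2.64 to 5.2".  Labels are 0 below the break and 1 at or above it.
    """
    if k != 2:
        raise NotImplementedError("only k=2 discretization is supported")
    s = pd.Series(values, dtype=float)
    x = np.sort(s.to_numpy())
    n = x.size
    if n < 2 or np.ptp(x) == 0:
        raise ValueError("need >= 2 distinct values for a 2-cluster split")
    best_ss, best_split = np.inf, None
    csum, csq = np.cumsum(x), np.cumsum(x**2)
    for m in range(1, n):  # low cluster = x[:m]
        if x[m - 1] == x[m]:
            continue  # identical values must share a cluster
        ss_lo = csq[m - 1] - csum[m - 1] ** 2 / m
        ss_hi = (csq[-1] - csq[m - 1]) - (csum[-1] - csum[m - 1]) ** 2 / (n - m)
        ss = ss_lo + ss_hi
        if ss < best_ss - 1e-12:
            best_ss, best_split = ss, m
    if best_split is None:
        raise ValueError("no valid 2-cluster split (all values identical)")
    brk = 0.5 * (x[best_split - 1] + x[best_split])
    labels = (s >= brk).astype(int)
    return DiscretizationResult(float(brk), labels, float(best_ss))


def make_elicit_care(coop, dom) -> pd.Series:
    """Elementwise OR of the cooperative-breeder and domesticated flags."""
    c, d = pd.Series(coop), pd.Series(dom)
    if len(c) != len(d):
        raise ValueError("flag vectors must have equal length")
    for v in (c, d):
        if not v.isin([0, 1]).all():
            raise ValueError("flags must be binary 0/1")
    out = ((c.to_numpy() + d.to_numpy()) > 0).astype(int)
    return pd.Series(out, index=c.index, name="elicit_care")


def engineer_traits(table: TraitTable) -> TraitTable:
    """Derive compound allocare sums and binary regimes in place.

    Adds ``allocare_sum``, ``allocare_sum_nocarry``, a discretized
    ``cooperative_breeder`` flag (two-cluster split of ``allocare_sum``)
    and ``elicit_care``.  An existing ``cooperative_breeder`` column is
    preserved (the flag is then only cross-checked against the split).
    """
    df = table.data.copy()
    if not set(ALLOCARE_COMPONENTS) <= set(df.columns):
        raise ValueError("allocare component columns required to engineer traits")
    df["allocare_sum"] = compound_allocare(df)
    df["allocare_sum_nocarry"] = compound_allocare(df, no_carry=True)
    split = kmeans_discretize_1d(df["allocare_sum"])
    if "cooperative_breeder" in df.columns:
        if not (df["cooperative_breeder"].to_numpy() == split.labels.to_numpy()).all():
            logger.warning(
                "input cooperative_breeder flags differ from the allocare_sum "
                "discretization (break %.4g)", split.break_point,
            )
    else:
        df["cooperative_breeder"] = split.labels
    if "domesticated" not in df.columns:
        raise ValueError("domesticated flag column required")
    df["elicit_care"] = make_elicit_care(df["cooperative_breeder"], df["domesticated"])
    out = TraitTable(df)
    out.validate(strict=False)
    return out
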