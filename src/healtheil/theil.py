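"""Population-weighted Theil index with exact within/between decomposition.

The statistic is the mean-log-deviation (Theil-L) form over provinces::

    T = Σ_i p_i · ln(p_i / y_i)

where ``p_i`` is province i's share of total population and ``y_i`` its
share of the total resource.  Grouping provinces into regions j with
population shares ``P_j`` and resource shares ``Y_j`` decomposes it exactly::

    T = T_within + T_between
      = Σ_j P_j · T_j   +   Σ_j P_j · ln(P_j / Y_j)

``T_j`` is the same statistic evaluated on within-group shares (province
shares renormalized by the group totals).  Every component is a relative
entropy, hence non-negative, and zero iff resource shares are proportional
to population shares.  Values are in nats (natural log) and unbounded above
— despite a common informal claim that the index lives in [0, 1].

Group contribution rates divide each component by the total:
``rate_j = P_j·T_j / T`` and ``rate_between = T_between / T``; they sum to 1
whenever T > 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import ResourcePanel

#: |Σ shares − 1| tolerance for validating share vectors.
SHARE_SUM_TOL = 1e-9
#: |T_total − T_within − T_between| tolerance for the decomposition identity.
IDENTITY_TOL = 1e-12


class ZeroShareError(ValueError):
    """A unit with positive population holds none of the resource."""


@dataclass(frozen=True)
class ShareVector:
    """Aligned population shares ``p`` and resource shares ``y`` over units."""

    labels: tuple[str, ...]
    p: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "y", y)
        if not (len(self.labels) == p.size == y.size):
            raise ValueError("labels, p and y must have equal length")
        if abs(p.sum() - 1.0) > SHARE_SUM_TOL or abs(y.sum() - 1.0) > SHARE_SUM_TOL:
            raise ValueError(
                f"shares must sum to 1 (got Σp={p.sum()!r}, Σy={y.sum()!r})"
            )
        if np.any(p <= 0):
            raise ValueError("population shares must be strictly positive")
        if np.any(y < 0):
            raise ValueError("resource shares must be non-negative")

    @classmethod
    def from_amounts(
        cls,
        labels: Sequence[str],
        populations: Sequence[float],
        amounts: Sequence[float],
        zero_policy: str = "error",
    ) -> "ShareVector":
        """Build shares from raw populations and resource amounts.

        ``zero_policy`` governs units with a zero resource amount: ``"error"``
        (default — the statistic would be infinite) raises
        :class:`ZeroShareError` naming the units; ``"drop"`` excludes them,
        renormalizes, and emits a warning.
        """
        pop = np.asarray(populations, dtype=float)
        amt = np.asarray(amounts, dtype=float)
        labels = tuple(labels)
        if zero_policy not in ("error", "drop"):
            raise ValueError(f"zero_policy must be 'error' or 'drop', got {zero_policy!r}")
        zero = amt == 0
        if zero.any():
            offenders = [labels[i] for i in np.flatnonzero(zero)]
            if zero_policy == "error":
                raise ZeroShareError(
                    "zero resource amount with positive population for: "
                    + ", ".join(offenders)
                )
            warnings.warn(
                f"dropping zero-resource unit(s) and renormalizing: {offenders}",
                stacklevel=2,
            )
            keep = ~zero
            labels = tuple(l for l, k in zip(labels, keep) if k)
            pop, amt = pop[keep], amt[keep]
        return cls(labels=labels, p=pop / pop.sum(), y=amt / amt.sum())


def theil_total(shares: ShareVector) -> float:
    """Mean-log-deviation Theil value Σ p·ln(p/y), in nats.

    Zero iff p == y elementwise; raises :class:`ZeroShareError` if any unit
    with positive population share has a zero resource share.
    """
    if np.any((shares.p > 0) & (shares.y == 0)):
        offenders = [
            shares.labels[i] for i in np.flatnonzero((shares.p > 0) & (shares.y == 0))
        ]
        raise ZeroShareError(f"zero resource share for unit(s): {offenders}")
    value = float(np.sum(shares.p * np.log(shares.p / shares.y)))
    # mathematically >= 0; rounding noise of order eps is clamped away
    return value if value > 0.0 else (0.0 if value > -SHARE_SUM_TOL else value)


@dataclass(frozen=True)
class GroupComponent:
    group: str
    P: float  # group population share
    Y: float  # group resource share
    T: float  # within-group Theil on renormalized shares
    weighted_within: float  # P * T
    contribution_rate: float | None = None


@dataclass(frozen=True)
class TheilDecomposition:
    resource: str
    year: int
    T_total: float
    T_between: float
    T_within: float
    groups: tuple[GroupComponent, ...]
    between_contribution_rate: float | None = None

    def group(self, name: str) -> GroupComponent:
        for g in self.groups:
            if g.group == name:
                return g
        raise KeyError(f"no group {name!r} in decomposition")


def _panel_shares(
    panel: ResourcePanel, resource: str, year: int, zero_policy: str
) -> tuple[ShareVector, dict[str, str]]:
    if panel.values_are_densities:
        raise ValueError("panel stores densities, not counts; Theil needs raw counts")
    subset = [
        rec
        for rec in panel.subset(year)
        if rec.resource(resource) is not None and rec.region is not None
    ]
    if len(subset) < 2:
        raise ValueError(
            f"need >= 2 provinces with {resource} counts and regions in {year}"
        )
    subset.sort(key=lambda rec: rec.province)
    shares = ShareVector.from_amounts(
        [rec.province for rec in subset],
        [rec.population for rec in subset],
        [rec.resource(resource) for rec in subset],
        zero_policy=zero_policy,
    )
    regions = {rec.province: rec.region for rec in subset}
    return shares, regions  # type: ignore[return-value]


def theil_decompose(
    panel: ResourcePanel,
    resource: str,
    year: int,
    zero_policy: str = "error",
    with_rates: bool = True,
) -> TheilDecomposition:
    """Decompose the Theil index for one (year, resource) by region.

    The total equals the ungrouped statistic exactly (decomposition theorem);
    the identity |T_total − T_within − T_between| < 1e-12 is enforced.
    """
    shares, regions = _panel_shares(panel, resource, year, zero_policy)
    groups = sorted({regions[label] for label in shares.labels})
    if len(groups) < 2:
        raise ValueError(f"need >= 2 regions with data in {year}, got {groups}")

    components = []
    T_within = 0.0
    T_between = 0.0
    for group in groups:
        idx = np.array([regions[l] == group for l in shares.labels])
        P_j = float(shares.p[idx].sum())
        Y_j = float(shares.y[idx].sum())
        if Y_j == 0:
            raise ZeroShareError(f"group {group!r} holds none of {resource}")
        inner = ShareVector(
            labels=tuple(l for l, k in zip(shares.labels, idx) if k),
            p=shares.p[idx] / P_j,
            y=shares.y[idx] / Y_j,
        )
        T_j = theil_total(inner)
        T_within += P_j * T_j
        T_between += P_j * math.log(P_j / Y_j)
        components.append(
            GroupComponent(group=group, P=P_j, Y=Y_j, T=T_j, weighted_within=P_j * T_j)
        )
    if -SHARE_SUM_TOL < T_between < 0.0:  # relative-entropy form, >= 0
        T_between = 0.0
    T_total = T_within + T_between
    assert abs(T_total - theil_total(shares)) < max(IDENTITY_TOL, 1e-12 * (1 + abs(T_total)))
    decomp = TheilDecomposition(
        resource=resource,
        year=int(year),
        T_total=T_total,
        T_between=T_between,
        T_within=T_within,
        groups=tuple(components),
    )
    return contribution_rates(decomp) if with_rates else decomp


def contribution_rates(decomp: TheilDecomposition) -> TheilDecomposition:
    """Fill each component's share of total inequality.

    Group j contributes ``P_j·T_j / T_total`` and the between-region term
    ``T_between / T_total``; the rates sum to 1.  With a zero total the rates
    are undefined and left as ``None``.
    """
    if decomp.T_total <= 0.0:
        return replace(
            decomp,
            between_contribution_rate=None,
            groups=tuple(replace(g, contribution_rate=None) for g in decomp.groups),
        )
    return replace(
        decomp,
        between_contribution_rate=decomp.T_between / decomp.T_total,
        groups=tuple(
            replace(g, contribution_rate=g.weighted_within / decomp.T_total)
            for g in decomp.groups
        ),
    )


def theil_trend(
    panel: ResourcePanel,
    resource: str,
    zero_policy: str = "error",
) -> list[TheilDecomposition]:
    """Per-year decompositions for one resource, sorted ascending by year.

    Years without usable data for the resource are skipped with a warning.
    """
    if len(panel.years) < 2:
        raise ValueError("trend needs a panel spanning >= 2 years")
    series = []
    for year in panel.years:
        try:
            series.append(theil_decompose(panel, resource, year, zero_policy=zero_policy))
        except (ValueError, ZeroShareError) as exc:
            warnings.warn(f"skipping {resource} in {year}: {exc}", stacklevel=2)
    return series


def trend_frame(series: Iterable[TheilDecomposition]) -> pd.DataFrame:
    """Tidy (year, component, value) rows: total/within/between per year."""
    rows = []
    for d in series:
        rows += [
            {"resource": d.resource, "year": d.year, "component": "total", "value": d.T_total},
            {"resource": d.resource, "year": d.year, "component": "within", "value": d.T_within},
            {"resource": d.resource, "year": d.year, "component": "between", "value": d.T_between},
        ]
    return pd.DataFrame(rows)


def region_within_frame(series: Iterable[TheilDecomposition]) -> pd.DataFrame:
    """Per-region within-group Theil values T_j by year."""
    rows = [
        {"resource": d.resource, "year": d.year, "region": g.group, "T_within_region": g.T}
        for d in series
        for g in d.groups
    ]
    return pd.DataFrame(rows)


def contribution_frame(series: Iterable[TheilDecomposition]) -> pd.DataFrame:
    """Contribution rates by year: one row per region plus the between term."""
    rows = []
    for d in series:
        for g in d.groups:
            rows.append(
                {"resource": d.resource, "year": d.year, "component": g.group,
                 "contribution_rate": g.contribution_rate}
            )
        rows.append(
            {"resource": d.resource, "year": d.year, "component": "between",
             "contribution_rate": d.between_contribution_rate}
        )
    return pd.DataFrame(rows)
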