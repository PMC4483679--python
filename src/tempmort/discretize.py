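"""Continuous region factors -> discrete states; percent changes -> risk labels.

Bayesian networks over discrete variables need discrete inputs, so the
continuous socioeconomic/demographic factors are cut into ordered states
(low / middle / high). Two routes are provided:

* **supervised** — recursive entropy-minimization splits with the
  Fayyad-Irani MDL stopping criterion, using the binary risk label as the
  class variable; candidate cuts sit at boundary midpoints between
  class-label changes, which makes the induced partition invariant to
  strictly increasing transformations of the factor;
* **manual** — an explicit interval scheme (with verbatim bracket types such
  as ``[5.18, 5.25]`` / ``(5.25, 12.31]``), the faithful path when
  reproducing a published set of splits.

Risk labels are binary: a region is *high risk* when its estimated percent
change per 1 degC beyond threshold is at least 1% (cold) or 10% (heat).
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gam import EffectEstimate

__all__ = [
    "Interval",
    "FactorScheme",
    "DiscretizationScheme",
    "supervised_splits",
    "apply_scheme",
    "label_risk",
    "RISK_THRESHOLDS",
    "DEFAULT_STATE_LABELS",
]

logger = logging.getLogger(__name__)

RISK_THRESHOLDS = {"cold": 1.0, "heat": 10.0}  # percent per degC

DEFAULT_STATE_LABELS = {
    1: ["all"],
    2: ["low", "high"],
    3: ["low", "middle", "high"],
}


def _labels_for(k: int) -> list[str]:
    if k in DEFAULT_STATE_LABELS:
        return list(DEFAULT_STATE_LABELS[k])
    return [f"level{i + 1}" for i in range(k)]


# ---------------------------------------------------------------------------
# schemes


_INTERVAL_RE = re.compile(
    r"^\s*([\[\(])\s*(-?\d+(?:\.\d+)?)\s*,\s*(-?\d+(?:\.\d+)?)\s*([\]\)])\s*$")


@dataclass(frozen=True)
class Interval:
    """One labeled interval with explicit endpoint closure."""

    lo: float
    hi: float
    lo_closed: bool
    hi_closed: bool
    label: str

    @classmethod
    def parse(cls, text: str, label: str) -> "Interval":
        m = _INTERVAL_RE.match(text)
        if not m:
            raise ValueError(f"cannot parse interval {text!r}")
        lo_b, lo, hi, hi_b = m.groups()
        return cls(float(lo), float(hi), lo_b == "[", hi_b == "]", label)

    def contains(self, x: float) -> bool:
        above = x > self.lo or (self.lo_closed and x == self.lo)
        below = x < self.hi or (self.hi_closed and x == self.hi)
        return above and below

    def __str__(self) -> str:
        return (f"{'[' if self.lo_closed else '('}{self.lo}, "
                f"{self.hi}{']' if self.hi_closed else ')'}")


@dataclass
class FactorScheme:
    """Discretization of one factor: either cut points with the automatic
    half-open convention (value at a cut belongs to the upper state) or an
    explicit manual interval list honoring printed bracket types."""

    factor: str
    cuts: list = field(default_factory=list)       # ascending cut points
    labels: list = field(default_factory=list)     # len(cuts) + 1 state names
    intervals: list | None = None                  # manual Interval list
    categorical: bool = False                      # pass-through factor

    def __post_init__(self):
        if self.categorical:
            return
        if self.intervals is not None:
            self.labels = [iv.label for iv in self.intervals]
            return
        self.cuts = sorted(float(c) for c in self.cuts)
        if len(self.cuts) != len(set(self.cuts)):
            raise ValueError(f"{self.factor}: duplicate cut points")
        if not self.labels:
            self.labels = _labels_for(len(self.cuts) + 1)
        if len(self.labels) != len(self.cuts) + 1:
            raise ValueError(f"{self.factor}: {len(self.cuts)} cuts need "
                             f"{len(self.cuts) + 1} labels")

    def assign(self, x: float) -> str:
        if self.categorical:
            return str(x)
        if self.intervals is not None:
            for iv in self.intervals:
                if iv.contains(x):
                    return iv.label
            # outside the outermost printed intervals: clamp to nearest
            logger.warning("%s: value %s outside scheme intervals; clamped",
                           self.factor, x)
            return (self.intervals[0].label if x < self.intervals[0].lo
                    else self.intervals[-1].label)
        idx = int(np.digitize([x], self.cuts, right=False)[0])
        return self.labels[idx]

    @property
    def state_labels(self) -> list[str]:
        return list(self.labels) if not self.categorical else []


@dataclass
class DiscretizationScheme:
    """Per-factor schemes; factors not listed raise on application."""

    factors: dict

    def to_json(self) -> str:
        obj = {}
        for name, fs in self.factors.items():
            if fs.categorical:
                obj[name] = {"categorical": True}
            elif fs.intervals is not None:
                obj[name] = {"intervals": [[str(iv), iv.label] for iv in fs.intervals]}
            else:
                obj[name] = {"cuts": fs.cuts, "labels": fs.labels}
        return json.dumps(obj, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DiscretizationScheme":
        obj = json.loads(text)
        factors = {}
        for name, spec in obj.items():
            if spec.get("categorical"):
                factors[name] = FactorScheme(name, categorical=True)
            elif "intervals" in spec:
                ivs = [Interval.parse(s, lab) for s, lab in spec["intervals"]]
                factors[name] = FactorScheme(name, intervals=ivs)
            else:
                factors[name] = FactorScheme(name, cuts=spec["cuts"],
                                             labels=spec.get("labels", []))
        return cls(factors)


# ---------------------------------------------------------------------------
# supervised (entropy/MDL) splitting


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _class_counts(y: np.ndarray, k: int) -> np.ndarray:
    return np.bincount(y, minlength=k)


def _best_boundary_cut(x: np.ndarray, y: np.ndarray, k: int):
    """Best single cut among boundary midpoints (class change between
    adjacent distinct x values); returns (cut, gain, left_mask) or None."""
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    n = len(xs)
    parent = _class_counts(ys, k)
    h_parent = _entropy(parent)
    best = None
    left = np.zeros(k, dtype=np.int64)
    for i in range(n - 1):
        left[ys[i]] += 1
        if xs[i + 1] <= xs[i]:
            continue
        # boundary point: the classes on the two sides of the gap differ
        # somewhere across the tie groups; the standard sufficient test is a
        # label change between the adjacent examples
        if ys[i + 1] == ys[i] and len(set(ys[xs == xs[i]])) == 1 \
                and len(set(ys[xs == xs[i + 1]])) == 1:
            continue
        right = parent - left
        n_l = left.sum()
        h = (n_l * _entropy(left) + (n - n_l) * _entropy(right)) / n
        gain = h_parent - h
        cut = (xs[i] + xs[i + 1]) / 2.0
        if best is None or gain > best[1] + 1e-12:
            best = (cut, gain, left.copy())
    return best


def _mdl_accepts(n: int, gain: float, parent: np.ndarray, left: np.ndarray,
                 right: np.ndarray) -> bool:
    k = int((parent > 0).sum())
    k1 = int((left > 0).sum())
    k2 = int((right > 0).sum())
    delta = (math.log2(3 ** k - 2)
             - (k * _entropy(parent) - k1 * _entropy(left) - k2 * _entropy(right)))
    threshold = (math.log2(n - 1) + delta) / n
    return gain > threshold


def best_single_cut(x, labels):
    """Best single cut point by information gain (boundary candidates).

    Returns ``(cut, gain)`` or ``None`` when no candidate exists. By
    Fayyad's boundary-point theorem the optimum over *all* midpoints is
    attained at a class-boundary midpoint, so restricting candidates loses
    nothing.
    """
    x = np.asarray(x, dtype=float)
    classes, y = np.unique(np.asarray(labels), return_inverse=True)
    best = _best_boundary_cut(x, y, len(classes))
    return None if best is None else (best[0], best[1])


def supervised_splits(x, labels, fallback: str = "median") -> list[float]:
    """Cut points by recursive entropy minimization with MDL stopping.

    Candidate cuts sit at midpoints between adjacent distinct values of
    ``x`` where the class labels change; each accepted cut recurses into
    both halves. When the MDL criterion rejects every cut, a single median
    cut is returned as the fallback (``fallback=None`` returns an empty
    list instead).
    """
    x = np.asarray(x, dtype=float)
    y_raw = np.asarray(labels)
    classes, y = np.unique(y_raw, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("supervised splitting needs both label classes present")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct factor values")
    k = len(classes)

    cuts: list[float] = []

    def recurse(mask: np.ndarray):
        xs, ys = x[mask], y[mask]
        if len(xs) < 2 or len(np.unique(xs)) < 2:
            return
        best = _best_boundary_cut(xs, ys, k)
        if best is None:
            return
        cut, gain, left_counts = best
        parent = _class_counts(ys, k)
        right_counts = parent - left_counts
        if not _mdl_accepts(len(xs), gain, parent, left_counts, right_counts):
            return
        cuts.append(cut)
        recurse(mask & (x < cut))
        recurse(mask & (x >= cut))

    recurse(np.ones(len(x), dtype=bool))
    cuts.sort()
    if not cuts and fallback == "median":
        cuts = [float(np.median(x))]
    return cuts


def build_scheme(table: pd.DataFrame, labels: pd.Series,
                 categorical: tuple = ("climatic_zone",),
                 manual: dict | None = None) -> DiscretizationScheme:
    """Supervised scheme for every numeric factor column of ``table``;
    ``manual`` entries (factor -> FactorScheme) override the automatic ones."""
    manual = manual or {}
    factors: dict[str, FactorScheme] = {}
    for col in table.columns:
        if col == "region_id":
            continue
        if col in manual:
            factors[col] = manual[col]
        elif col in categorical:
            factors[col] = FactorScheme(col, categorical=True)
        else:
            cuts = supervised_splits(table[col].to_numpy(dtype=float), labels)
            factors[col] = FactorScheme(col, cuts=cuts)
    return DiscretizationScheme(factors)


def apply_scheme(table: pd.DataFrame, scheme: DiscretizationScheme) -> pd.DataFrame:
    """Map every factor column to its discrete state labels.

    Automatic cut lists use the half-open convention ``[a, b)`` — a value
    equal to a cut belongs to the upper state; manual interval lists honor
    their printed bracket types verbatim.
    """
    out = pd.DataFrame()
    if "region_id" in table.columns:
        out["region_id"] = table["region_id"]
    for col in table.columns:
        if col == "region_id":
            continue
        if col not in scheme.factors:
            raise KeyError(f"scheme does not cover factor {col!r}")
        fs = scheme.factors[col]
        vals = table[col]
        if fs.categorical:
            out[col] = vals.astype(str)
        else:
            mapped = [fs.assign(float(v)) for v in vals]
            out[col] = pd.Categorical(mapped, categories=fs.state_labels,
                                      ordered=True)
    if out.drop(columns=["region_id"], errors="ignore").isna().any().any():
        raise ValueError("discretization produced missing states")
    return out


def label_risk(effect: EffectEstimate) -> str:
    """Binary label: high risk iff percent change >= 1 (cold) / 10 (heat)."""
    if effect.side not in RISK_THRESHOLDS:
        raise ValueError(f"unknown side {effect.side!r}")
    return ("high_risk" if effect.percent_change >= RISK_THRESHOLDS[effect.side]
            else "low_risk")
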