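"""Inter-method agreement statistics for relative-validity analysis.

Two dietary-assessment methods score the same participants; relative
validity asks how well the brief method tracks the reference one. Two
statistics are used:

* Spearman rank correlation on raw nutrient intakes — midranks for ties,
  the correlation is the Pearson correlation of the rank vectors, and the
  two-sided p-value uses the t approximation
  ``t = rho * sqrt((n - 2) / (1 - rho**2))`` on ``n - 2`` degrees of
  freedom (the convention of mainstream statistics software at these
  sample sizes). An exact permutation p-value is available for small n.

* Cohen kappa on categorical classifications — adequacy classes for the
  micronutrients, 1000 kJ energy bins for energy. The p-value tests
  kappa = 0 with the asymptotic null standard error

  ``SE0 = sqrt((pe + pe^2 - sum_i pi.*p.i*(pi. + p.i)) / (n*(1 - pe)^2))``

  and a two-sided normal tail on ``z = kappa / SE0``. If either method
  assigns every participant the same class the statistic is undefined and
  the result is flagged degenerate ("constants — no statistics computed"),
  never reported as a number.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
from scipy import stats

from .composition import NRVTable, Nutrient, ValidationError
from .engine import AdequacyClass, NutrientProfile, classify_adequacy

__all__ = [
    "ConstantInputError",
    "AgreementResult",
    "spearman",
    "spearman_exact_p",
    "cohen_kappa",
    "bin_energy",
    "interpret_kappa",
    "validity_table",
]

#: Floor below which a p-value is reported (used when |rho| = 1 exactly).
P_FLOOR = float(np.finfo(float).tiny)


class ConstantInputError(ValueError):
    """A statistic is undefined because an input vector is constant."""


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Ties receive midranks. Raises :class:`ConstantInputError` if either
    vector is constant (the correlation is undefined); ``|rho| = 1``
    reports a p-value at the machine floor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman requires two equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise ValidationError(f"spearman requires n >= 3, got n={n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("spearman requires finite values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("constant vector: rank correlation undefined")

    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))
    rho = max(-1.0, min(1.0, rho))

    if abs(rho) == 1.0:
        return rho, P_FLOOR
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def spearman_exact_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided permutation p-value for the Spearman correlation.

    Enumerates all n! pairings (n <= 8) and counts those with
    ``|rho| >= |rho_observed|``. Slow by design; doubles as an independent
    check on the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 8:
        raise ValidationError("exact permutation p-value limited to n <= 8")
    rho_obs, _ = spearman(x, y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho_perm, _ = spearman(x, y[list(perm)])
        if abs(rho_perm) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def cohen_kappa(
    a: Sequence[Hashable],
    b: Sequence[Hashable],
    labels: Sequence[Hashable] | None = None,
    *,
    weights: str | None = None,
) -> tuple[float | None, float | None, bool]:
    """Cohen kappa between two classifications of the same subjects.

    Returns ``(kappa, p, degenerate)``. ``kappa = (po - pe) / (1 - pe)``
    with observed agreement ``po`` and chance agreement ``pe`` from the two
    marginal distributions. The two-sided p-value uses the asymptotic null
    standard error (see module docstring); it is ``None`` under
    ``weights="linear"``, where only the point estimate is computed.

    If either sequence contains a single distinct label the statistic is
    undefined: returns ``(None, None, True)``.
    """
    a = list(a)
    b = list(b)
    if len(a) != len(b):
        raise ValidationError(f"length mismatch: {len(a)} vs {len(b)}")
    n = len(a)
    if n < 2:
        raise ValidationError(f"kappa requires n >= 2, got n={n}")
    if len(set(a)) < 2 or len(set(b)) < 2:
        return None, None, True

    table, _ = crosstab(a, b, labels)
    k = table.shape[0]
    p = table / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(row @ col)

    if weights == "linear":
        idx = np.arange(k)
        w = np.abs(idx[:, None] - idx[None, :]).astype(float)
        denom = float((w * np.outer(row, col)).sum())
        kappa = 1.0 - float((w * p).sum()) / denom
        return kappa, None, False
    if weights is not None:
        raise ValidationError(f"unsupported weights: {weights!r}")

    kappa = (po - pe) / (1.0 - pe)
    var0 = (pe + pe * pe - float((row * col * (row + col)).sum())) / (n * (1.0 - pe) ** 2)
    if var0 <= 0.0:
        # degenerate null distribution (e.g. the two methods' label supports
        # are disjoint, so pe = 0): no evidence either way unless kappa != 0
        pval = 1.0 if kappa == 0.0 else 0.0
    else:
        z = kappa / math.sqrt(var0)
        pval = 2.0 * stats.norm.sf(abs(z))
    return float(kappa), float(pval), False


def crosstab(
    a: Sequence[Hashable], b: Sequence[Hashable], labels: Sequence[Hashable] | None = None
) -> tuple[np.ndarray, list[Hashable]]:
    """Square contingency table of paired labels over a shared label set.

    When ``labels`` is not given, the set is the sorted union of labels
    observed in either sequence.
    """
    if labels is None:
        labels = sorted(set(a) | set(b))
    index = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)), dtype=int)
    for ai, bi in zip(a, b, strict=True):
        table[index[ai], index[bi]] += 1
    return table, list(labels)


def bin_energy(values: Sequence[float], width: float = 1000.0) -> np.ndarray:
    """Assign energy intakes (kJ/day) to half-open bins [k*width, (k+1)*width)."""
    if width <= 0:
        raise ValidationError(f"bin width must be > 0, got {width}")
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValidationError("energy values must be >= 0")
    return np.floor(values / width).astype(int)


#: Landis–Koch interpretation ladder; upper bounds inclusive, so the
#: moderate band is 0.41 <= kappa <= 0.60 and substantial 0.61 <= kappa <= 0.80.
_KAPPA_BANDS = [
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
]


def interpret_kappa(kappa: float) -> str:
    """Qualitative agreement label for a kappa value on the Landis–Koch scale.

    The scale's band edges are stated at two-decimal resolution, so the
    value is rounded to 2 decimals before banding (0.803 is substantial,
    not almost perfect).
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValidationError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa < 0:
        return "poor"
    rounded = round(kappa, 2)
    for upper, label in _KAPPA_BANDS:
        if rounded <= upper:
            return label
    return "almost perfect"


@dataclass(frozen=True)
class AgreementResult:
    """Agreement between two methods for one nutrient under one condition."""

    nutrient: Nutrient
    condition: str  # "with_supplements" | "food_only"
    rho: float | None
    rho_p: float | None
    kappa: float | None
    kappa_p: float | None
    degenerate: bool
    crosstab: np.ndarray
    labels: tuple
    class_margins: dict  # method -> {label: (n, pct)}
    n: int

    @property
    def kappa_label(self) -> str | None:
        return None if self.kappa is None else interpret_kappa(self.kappa)


def _margins(classes: Sequence[Hashable], labels: Sequence[Hashable]) -> dict:
    n = len(classes)
    out = {}
    for lab in labels:
        count = sum(1 for c in classes if c == lab)
        out[lab] = (count, 100.0 * count / n)
    return out


def validity_table(
    profiles_a: Sequence[NutrientProfile],
    profiles_b: Sequence[NutrientProfile],
    nrv: NRVTable,
    *,
    energy_bin_width: float = 1000.0,
) -> list[AgreementResult]:
    """Full agreement table between two methods' nutrient profiles.

    ``profiles_a`` and ``profiles_b`` hold the same participants in the
    same order and may mix both supplement conditions (paired by position
    within each condition). Per condition and nutrient: Spearman rho on
    raw intakes; Cohen kappa on 1000 kJ bins for energy and on adequacy
    classes for each micronutrient, with per-method class margins.
    """
    if len(profiles_a) != len(profiles_b):
        raise ValidationError("method A and method B profile lists differ in length")

    results: list[AgreementResult] = []
    for included, condition in ((True, "with_supplements"), (False, "food_only")):
        sub_a = [p for p in profiles_a if p.supplements_included == included]
        sub_b = [p for p in profiles_b if p.supplements_included == included]
        if not sub_a and not sub_b:
            continue
        if len(sub_a) != len(sub_b):
            raise ValidationError(f"condition {condition}: participant mismatch between methods")
        ids_a = [p.participant_id for p in sub_a]
        ids_b = [p.participant_id for p in sub_b]
        if any(ids_a) and any(ids_b) and ids_a != ids_b:
            raise ValidationError(f"condition {condition}: participant ids differ between methods")

        classes_a = [classify_adequacy(p, nrv) for p in sub_a]
        classes_b = [classify_adequacy(p, nrv) for p in sub_b]

        for nutrient in Nutrient:
            xa = [p[nutrient] for p in sub_a]
            xb = [p[nutrient] for p in sub_b]
            try:
                rho, rho_p = spearman(xa, xb)
            except ConstantInputError:
                rho, rho_p = None, None

            if nutrient is Nutrient.ENERGY:
                la = [int(v) for v in bin_energy(xa, energy_bin_width)]
                lb = [int(v) for v in bin_energy(xb, energy_bin_width)]
                labels = sorted(set(la) | set(lb))
            else:
                la = [c[nutrient] for c in classes_a]
                lb = [c[nutrient] for c in classes_b]
                labels = list(AdequacyClass)

            kappa, kappa_p, degenerate = cohen_kappa(la, lb, labels)
            table, _ = crosstab(la, lb, labels)
            results.append(
                AgreementResult(
                    nutrient=nutrient,
                    condition=condition,
                    rho=rho,
                    rho_p=rho_p,
                    kappa=kappa,
                    kappa_p=kappa_p,
                    degenerate=degenerate,
                    crosstab=table,
                    labels=tuple(labels),
                    class_margins={"a": _margins(la, labels), "b": _margins(lb, labels)},
                    n=len(sub_a),
                )
            )
    return results
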