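"""Linguistic fuzzy-logic forecaster and the SMAPE-comparison classifier.

The forecaster models a time series in three layers:

* the inverse fuzzy transform of the series (``ftransform.decompose``)
  gives a trend-cycle described by a short component vector X_1..X_n;
* the dynamics of the components — their values, first differences
  dX_i = X_i - X_{i-1} and second differences — are summarized as fuzzy
  IF-THEN rules over *evaluative expressions* ("more or less small",
  "negative medium", ...), induced automatically from the data;
* the seasonal residual is forecast autoregressively.

A *rule signature* such as ``S(t)&dS(t) -> dS(t+1)`` fixes which variables
appear in the antecedent and which is forecast.  Future components are
obtained by repeatedly firing the best-matching rule (a simplified,
deterministic stand-in for perception-based logical deduction: the rule
with the highest minimum antecedent membership wins and its consequent's
centroid, mapped back to the variable's context, is the prediction).
Trend and seasonal forecasts are summed into the series forecast, and
forecast quality is scored by SMAPE.

Classification of an ECG cycle works by appending the tested cycle to a
"healthy" and to a "sick" learning series, fitting the best predictor on
each learning block, and comparing the two SMAPE values on the tested
block: the smaller SMAPE names the class, with ties going to sick.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .ftransform import Decomposition, FuzzyPartition, decompose

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluativeExpression",
    "Context",
    "RuleSignature",
    "FuzzyRule",
    "LinguisticDescription",
    "ComponentSeries",
    "SeasonalAR",
    "ForecastModel",
    "ForecastResult",
    "LflfConfig",
    "SmapeClassification",
    "DEFAULT_SIGNATURE_MENU",
    "component_differences",
    "linguistic_eval",
    "generate_rules",
    "deduce",
    "fit_seasonal",
    "fit_forecaster",
    "forecast",
    "smape",
    "select_best_predictor",
    "verdict_from_smape",
    "classify_by_smape",
]


# ---------------------------------------------------------------------------
# Evaluative expressions
# ---------------------------------------------------------------------------
#
# Expressions are trapezoids over a normalized context [0, 1] (signed
# contexts mirror them onto [-1, 0]).  "small" anchors at 0, "medium" at
# 0.5, "big" at 1; hedges narrow (ex, si, ve) or widen (ml, ro, qr, vr)
# the trapezoid.  A dedicated zero expression "ze" (a narrow spike at 0
# with centroid exactly 0) exists for signed scales so that vanishing
# differences deduce to exactly zero.

# hedge -> (plateau end, support end) for "small"; "big" mirrors these.
_SM_SHAPES: dict[str, tuple[float, float]] = {
    "ex": (0.05, 0.15),
    "si": (0.08, 0.22),
    "ve": (0.12, 0.30),
    "": (0.17, 0.40),
    "ml": (0.22, 0.50),
    "ro": (0.28, 0.60),
    "qr": (0.35, 0.70),
    "vr": (0.42, 0.80),
}
# hedge -> (plateau half-width, support half-width) around 0.5 for "medium".
_ME_SHAPES: dict[str, tuple[float, float]] = {
    "": (0.05, 0.25),
    "ml": (0.08, 0.32),
    "ro": (0.12, 0.40),
    "qr": (0.16, 0.45),
    "vr": (0.20, 0.50),
}
_ZE_HALFWIDTH = 0.05

_HEDGE_ORDER = ("ex", "si", "ve", "", "ml", "ro", "qr", "vr")
_ATOMIC_ORDER = ("ze", "sm", "me", "bi")


def _trapezoid(atomic: str, hedge: str) -> tuple[float, float, float, float]:
    """Support/plateau breakpoints (foot, top, top, foot) on the unit scale."""
    if atomic == "sm":
        top, foot = _SM_SHAPES[hedge]
        return (0.0, 0.0, top, foot)
    if atomic == "bi":
        top, foot = _SM_SHAPES[hedge]
        return (1.0 - foot, 1.0 - top, 1.0, 1.0)
    if atomic == "me":
        ht, hf = _ME_SHAPES[hedge]
        return (0.5 - hf, 0.5 - ht, 0.5 + ht, 0.5 + hf)
    if atomic == "ze":
        return (-_ZE_HALFWIDTH, 0.0, 0.0, _ZE_HALFWIDTH)
    raise ValueError(f"unknown atomic term {atomic!r}")


def _trap_membership(u: float, trap: tuple[float, float, float, float]) -> float:
    a, b, c, d = trap
    if u < a or u > d:
        return 0.0
    if b <= u <= c:
        return 1.0
    if u < b:
        return (u - a) / (b - a)
    return (d - u) / (d - c)


def _trap_centroid(trap: tuple[float, float, float, float]) -> float:
    a, b, c, d = trap
    parts = []
    if b > a:
        parts.append(((b - a) / 2.0, a + 2.0 * (b - a) / 3.0))
    if c > b:
        parts.append((c - b, (b + c) / 2.0))
    if d > c:
        parts.append(((d - c) / 2.0, c + (d - c) / 3.0))
    if not parts:
        return a
    area = sum(w for w, _ in parts)
    return sum(w * x for w, x in parts) / area


def _trap_area(trap: tuple[float, float, float, float]) -> float:
    a, b, c, d = trap
    return (c - b) + (b - a) / 2.0 + (d - c) / 2.0


@dataclass(frozen=True)
class EvaluativeExpression:
    """A linguistic value such as "ml sm" (more or less small) or "-me".

    ``sign`` is +1 or -1 and only meaningful on signed contexts; the zero
    expression ("ze") has sign 0.  ``hedge`` is one of the standard
    abbreviations (ex, si, ve, ml, ro, qr, vr) or "" for the bare term.
    """

    atomic: str
    hedge: str = ""
    sign: int = 1

    def __post_init__(self) -> None:
        if self.atomic not in _ATOMIC_ORDER:
            raise ValueError(f"unknown atomic term {self.atomic!r}")
        if self.atomic == "ze":
            object.__setattr__(self, "sign", 0)
            object.__setattr__(self, "hedge", "")
            return
        if self.atomic == "me" and self.hedge not in _ME_SHAPES:
            raise ValueError(f"hedge {self.hedge!r} is not defined for 'me'")
        if self.atomic in ("sm", "bi") and self.hedge not in _SM_SHAPES:
            raise ValueError(f"hedge {self.hedge!r} is not defined for {self.atomic!r}")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")

    @property
    def trapezoid(self) -> tuple[float, float, float, float]:
        return _trapezoid(self.atomic, self.hedge)

    def membership(self, u: float) -> float:
        """Membership at a normalized value: u in [0,1], or [-1,1] if signed."""
        if self.atomic == "ze":
            return _trap_membership(u, self.trapezoid)
        if self.sign < 0:
            u = -u
        if u < 0.0:
            return 0.0
        return _trap_membership(u, self.trapezoid)

    def centroid(self) -> float:
        """Centroid on the normalized scale, carrying the sign."""
        if self.atomic == "ze":
            return 0.0
        return self.sign * _trap_centroid(self.trapezoid)

    def specificity(self) -> float:
        """Narrower expressions are more specific (used for tie-breaking)."""
        return 1.0 / _trap_area(self.trapezoid)

    def render(self) -> str:
        if self.atomic == "ze":
            return "ze"
        body = f"{self.hedge} {self.atomic}" if self.hedge else self.atomic
        return f"-{body}" if self.sign < 0 else body

    @classmethod
    def parse(cls, text: str) -> "EvaluativeExpression":
        s = text.strip()
        sign = 1
        if s.startswith("-") or s.startswith("−"):
            sign = -1
            s = s[1:].strip()
        if s == "ze":
            return cls(atomic="ze")
        parts = s.split()
        if len(parts) == 1:
            return cls(atomic=parts[0], sign=sign)
        if len(parts) == 2:
            return cls(atomic=parts[1], hedge=parts[0], sign=sign)
        raise ValueError(f"cannot parse evaluative expression {text!r}")

    def _sort_key(self):
        return (
            self.sign * _ATOMIC_ORDER.index(self.atomic) if self.atomic != "ze" else 0,
            _ATOMIC_ORDER.index(self.atomic),
            _HEDGE_ORDER.index(self.hedge) if self.atomic != "ze" else -1,
        )


def _expression_bank(signed: bool) -> list[EvaluativeExpression]:
    bank: list[EvaluativeExpression] = []
    if signed:
        bank.append(EvaluativeExpression(atomic="ze"))
    for atomic in ("sm", "me", "bi"):
        hedges = _ME_SHAPES if atomic == "me" else _SM_SHAPES
        for hedge in hedges:
            bank.append(EvaluativeExpression(atomic=atomic, hedge=hedge, sign=1))
            if signed:
                bank.append(EvaluativeExpression(atomic=atomic, hedge=hedge, sign=-1))
    return bank


@dataclass(frozen=True)
class Context:
    """Normalization range of one linguistic variable.

    Unsigned contexts map [lo, hi] onto [0, 1]; signed contexts (used for
    differences, which carry a sign) are symmetric around zero and map
    [-m, m] onto [-1, 1] with m = max(|lo|, |hi|).
    """

    lo: float
    hi: float
    signed: bool = False

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"context bounds out of order: ({self.lo}, {self.hi})")

    @classmethod
    def from_values(cls, values: np.ndarray, signed: bool) -> "Context":
        """Data-driven context; a (numerically) zero data range expands to unit width.

        Ranges below 1e-9 relative to the value magnitude are float noise
        (e.g. the jitter in the transform components of a constant series)
        and are treated as constant rather than stretched onto the scale.
        """
        lo, hi = float(np.min(values)), float(np.max(values))
        tiny = 1e-9 * max(1.0, abs(lo), abs(hi))
        if signed:
            m = max(abs(lo), abs(hi))
            if m <= tiny:
                m = 0.5
            return cls(lo=-m, hi=m, signed=True)
        if hi - lo <= tiny:
            mid = (lo + hi) / 2.0
            lo, hi = mid - 0.5, mid + 0.5
        return cls(lo=lo, hi=hi, signed=False)

    def normalize(self, value: float) -> float:
        if self.hi == self.lo:
            raise ValueError(f"degenerate context ({self.lo}, {self.hi})")
        if self.signed:
            m = max(abs(self.lo), abs(self.hi))
            u = float(np.clip(value / m, -1.0, 1.0))
            # values that are zero up to float noise count as exactly zero
            return 0.0 if abs(u) <= 1e-9 else u
        return float(np.clip((value - self.lo) / (self.hi - self.lo), 0.0, 1.0))

    def denormalize(self, u: float) -> float:
        if self.signed:
            m = max(abs(self.lo), abs(self.hi))
            return u * m
        return self.lo + u * (self.hi - self.lo)


def linguistic_eval(value: float, context: Context | tuple[float, float]) -> tuple[EvaluativeExpression, float]:
    """Best-matching evaluative expression for a value in a context.

    Returns the expression of maximal membership at the normalized value
    (ties resolved toward the more specific expression, then toward the
    positive sign) together with its membership degree.
    """
    if isinstance(context, tuple):
        context = Context(lo=float(context[0]), hi=float(context[1]), signed=context[0] < 0 < context[1])
    if context.hi == context.lo:
        raise ValueError(f"degenerate context ({context.lo}, {context.hi})")
    u = context.normalize(value)
    best: tuple[float, float, int, EvaluativeExpression] | None = None
    for expr in _expression_bank(context.signed):
        mu = expr.membership(u)
        if mu <= 0.0:
            continue
        key = (mu, expr.specificity(), expr.sign)
        if best is None or key > best[:3]:
            best = (*key, expr)
    if best is None:  # cannot happen: the bank covers the whole scale
        raise RuntimeError("no expression matched; expression bank does not cover the scale")
    return best[3], best[0]


# ---------------------------------------------------------------------------
# Rule signatures and variables
# ---------------------------------------------------------------------------

_VAR_RE = re.compile(r"^(S|dS|d2S)\(t(?:([+-])(\d+))?\)$")


def _parse_var(name: str) -> tuple[str, int]:
    m = _VAR_RE.match(name.replace(" ", ""))
    if not m:
        raise ValueError(f"unknown linguistic variable {name!r}")
    base = m.group(1)
    lag = 0
    if m.group(2):
        lag = int(m.group(3)) * (1 if m.group(2) == "+" else -1)
    return base, lag


def _var_signed(name: str) -> bool:
    base, _ = _parse_var(name)
    return base in ("dS", "d2S")


_MIN_INDEX = {"S": 0, "dS": 1, "d2S": 2}


def _var_value(name: str, X: np.ndarray, i: int) -> float:
    """Value of a variable at component index i (0-based); X are components."""
    base, lag = _parse_var(name)
    j = i + lag
    if base == "S":
        return float(X[j])
    if base == "dS":
        return float(X[j] - X[j - 1])
    return float(X[j] - 2.0 * X[j - 1] + X[j - 2])


@dataclass(frozen=True)
class RuleSignature:
    """Which variables form the antecedent and which is forecast.

    Variables are the trend-cycle components S, their differences dS and
    second differences d2S, each with a time lag, e.g. ``S(t)``, ``dS(t-1)``.
    The consequent is one of S(t+1), dS(t+1), d2S(t+1).
    """

    antecedents: tuple[str, ...]
    consequent: str

    def __post_init__(self) -> None:
        if not self.antecedents:
            raise ValueError("a signature needs at least one antecedent variable")
        for v in self.antecedents:
            base, lag = _parse_var(v)
            if lag > 0:
                raise ValueError(f"antecedent {v!r} must not look into the future")
        base, lag = _parse_var(self.consequent)
        if lag != 1:
            raise ValueError(f"consequent must be at lag t+1, got {self.consequent!r}")

    def render(self) -> str:
        return f"{'&'.join(self.antecedents)} -> {self.consequent}"

    @classmethod
    def parse(cls, text: str) -> "RuleSignature":
        lhs, _, rhs = text.partition("->")
        if not rhs:
            raise ValueError(f"signature {text!r} has no '->'")
        ants = tuple(v.strip() for v in lhs.split("&") if v.strip())
        return cls(antecedents=ants, consequent=rhs.strip())

    def index_range(self, n_components: int) -> range:
        """Valid component indices i at which every variable is defined."""
        lo = 0
        hi = n_components - 1
        for v in (*self.antecedents, self.consequent):
            base, lag = _parse_var(v)
            lo = max(lo, _MIN_INDEX[base] - lag)
            hi = min(hi, n_components - 1 - lag)
        return range(lo, hi + 1)


@dataclass(frozen=True)
class FuzzyRule:
    """IF <var is expr> AND ... THEN <var is expr>, with its data support."""

    antecedents: tuple[tuple[str, EvaluativeExpression], ...]
    consequent: tuple[str, EvaluativeExpression]
    support: int = 1

    def render(self) -> str:
        lhs = " AND ".join(f"{v} is {e.render()}" for v, e in self.antecedents)
        v, e = self.consequent
        return f"IF {lhs} THEN {v} is {e.render()}"

    @classmethod
    def parse(cls, text: str) -> "FuzzyRule":
        m = re.match(r"^IF (.+) THEN (.+)$", text.strip())
        if not m:
            raise ValueError(f"cannot parse rule {text!r}")

        def parse_atom(chunk: str) -> tuple[str, EvaluativeExpression]:
            var, _, expr = chunk.partition(" is ")
            if not expr:
                raise ValueError(f"cannot parse clause {chunk!r}")
            return var.strip(), EvaluativeExpression.parse(expr)

        ants = tuple(parse_atom(c) for c in m.group(1).split(" AND "))
        return cls(antecedents=ants, consequent=parse_atom(m.group(2)))


@dataclass
class LinguisticDescription:
    """An induced rule base with its signature and normalization contexts."""

    rules: list[FuzzyRule]
    signature: RuleSignature
    contexts: dict[str, Context]

    def render(self) -> str:
        return "\n".join(r.render() for r in self.rules)


@dataclass
class ComponentSeries:
    """Fuzzy-transform components with their first and second differences."""

    X: np.ndarray
    dX: np.ndarray
    d2X: np.ndarray


def component_differences(X) -> ComponentSeries:
    """First differences dX_i = X_i - X_{i-1} and second differences thereof."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 1 or len(X) < 3:
        raise ValueError(f"need at least 3 components, got {len(np.atleast_1d(X))}")
    dX = np.diff(X)
    return ComponentSeries(X=X, dX=dX, d2X=np.diff(dX))


def _build_contexts(X: np.ndarray, signature: RuleSignature) -> dict[str, Context]:
    idx = signature.index_range(len(X))
    contexts = {}
    for var in (*signature.antecedents, signature.consequent):
        vals = np.array([_var_value(var, X, i) for i in idx])
        contexts[var] = Context.from_values(vals, signed=_var_signed(var))
    return contexts


def generate_rules(cs: ComponentSeries | np.ndarray, signature: RuleSignature) -> LinguisticDescription:
    """Induce one candidate rule per valid time index, then merge and resolve.

    Duplicate rules merge with summed support; rules with identical
    antecedent expressions but different consequents keep the one with the
    higher support (first induced wins ties).  The returned rule order is
    canonicalized so equal inputs always give identical descriptions.
    """
    X = cs.X if isinstance(cs, ComponentSeries) else np.asarray(cs, dtype=float)
    idx = signature.index_range(len(X))
    if len(idx) < 1:
        raise ValueError(
            f"{len(X)} components are too few to instantiate signature {signature.render()}"
        )
    contexts = _build_contexts(X, signature)
    merged: dict[tuple, FuzzyRule] = {}
    order: dict[tuple, int] = {}
    for pos, i in enumerate(idx):
        ants = tuple(
            (v, linguistic_eval(_var_value(v, X, i), contexts[v])[0]) for v in signature.antecedents
        )
        cons = (
            signature.consequent,
            linguistic_eval(_var_value(signature.consequent, X, i), contexts[signature.consequent])[0],
        )
        key = (ants, cons)
        if key in merged:
            merged[key] = replace(merged[key], support=merged[key].support + 1)
        else:
            merged[key] = FuzzyRule(antecedents=ants, consequent=cons)
            order[key] = pos
    # resolve contradictions: same antecedents, different consequents
    by_ant: dict[tuple, FuzzyRule] = {}
    for key, rule in merged.items():
        prev = by_ant.get(rule.antecedents)
        if prev is None:
            by_ant[rule.antecedents] = rule
        elif rule.support > prev.support or (
            rule.support == prev.support
            and order[(rule.antecedents, rule.consequent)] < order[(prev.antecedents, prev.consequent)]
        ):
            by_ant[rule.antecedents] = rule
    rules = sorted(
        by_ant.values(),
        key=lambda r: tuple(e._sort_key() for _, e in r.antecedents),
    )
    return LinguisticDescription(rules=rules, signature=signature, contexts=contexts)


def deduce(description: LinguisticDescription, current: Mapping[str, float]) -> float:
    """Fire the best-matching rule and return a crisp consequent value.

    Each rule fires with the minimum membership of its antecedent
    expressions at the (normalized) current values; the rule with the
    highest firing degree wins, ties going to the more specific rule and
    then to the canonical order.  The output is the centroid of the winning
    consequent expression mapped back onto the consequent's context.  If no
    rule fires at all, the nearest rule by antecedent-centroid distance is
    used instead and the fallback is logged.
    """
    if not description.rules:
        raise ValueError("cannot deduce from an empty linguistic description")
    for var in description.signature.antecedents:
        if var not in current:
            raise ValueError(f"current values are missing antecedent variable {var!r}")
    u = {v: description.contexts[v].normalize(float(current[v])) for v in description.signature.antecedents}

    best_rule = None
    best_key: tuple[float, float] | None = None
    for rule in description.rules:
        degree = min(expr.membership(u[v]) for v, expr in rule.antecedents)
        spec = sum(expr.specificity() for _, expr in rule.antecedents)
        key = (degree, spec)
        if best_key is None or key > best_key:
            best_key = key
            best_rule = rule
    assert best_rule is not None
    if best_key[0] <= 0.0:
        # no rule covers the current state: fall back to the nearest rule
        def dist(rule: FuzzyRule) -> float:
            return sum((u[v] - expr.centroid()) ** 2 for v, expr in rule.antecedents)

        best_rule = min(description.rules, key=dist)
        logger.warning(
            "deduction fallback: no rule fired, using nearest rule %r", best_rule.render()
        )
    var, expr = best_rule.consequent
    return description.contexts[var].denormalize(expr.centroid())


# ---------------------------------------------------------------------------
# Seasonal residual: autoregressive least-squares model
# ---------------------------------------------------------------------------


@dataclass
class SeasonalAR:
    """AR(p) model of the seasonal residual, fit by least squares (no intercept)."""

    coef: np.ndarray
    order: int

    def forecast(self, history: np.ndarray, horizon: int) -> np.ndarray:
        buf = list(np.asarray(history, dtype=float)[-self.order :])
        out = []
        for _ in range(horizon):
            nxt = float(np.dot(self.coef, buf[::-1]))
            out.append(nxt)
            buf.append(nxt)
            buf.pop(0)
        return np.array(out)


def _fit_ar(x: np.ndarray, order: int) -> np.ndarray:
    rows = len(x) - order
    D = np.column_stack([x[order - lag - 1 : order - lag - 1 + rows] for lag in range(order)])
    # column `lag` holds x_{t-1-lag}; target is x_t
    y = x[order:]
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    return coef


def fit_seasonal(seasonal, order: int | None = None, max_order: int = 5) -> SeasonalAR:
    """Least-squares AR fit of the residual; order picked on a holdout tail.

    When ``order`` is None, orders 1..max_order are compared by one-step
    squared error on the last quarter of the residual and the best is
    refit on the full series.
    """
    x = np.asarray(seasonal, dtype=float)
    if x.ndim != 1:
        raise ValueError("seasonal residual must be 1-D")
    if order is not None:
        if len(x) < order + 1:
            raise ValueError(f"need at least order+1={order + 1} points, got {len(x)}")
        return SeasonalAR(coef=_fit_ar(x, order), order=order)
    candidates = [p for p in range(1, max_order + 1) if len(x) >= 2 * (p + 1)]
    if not candidates:
        if len(x) < 2:
            raise ValueError(f"need at least 2 points to fit a seasonal model, got {len(x)}")
        candidates = [1]
    n_hold = max(1, len(x) // 4)
    best_order, best_err = candidates[0], math.inf
    for p in candidates:
        head = x[:-n_hold]
        if len(head) < p + 1:
            continue
        coef = _fit_ar(head, p)
        # one-step-ahead predictions over the holdout
        errs = []
        for t in range(len(x) - n_hold, len(x)):
            lags = x[t - p : t][::-1]
            errs.append((float(np.dot(coef, lags)) - x[t]) ** 2)
        err = float(np.mean(errs))
        if err < best_err:
            best_order, best_err = p, err
    return SeasonalAR(coef=_fit_ar(x, best_order), order=best_order)


# ---------------------------------------------------------------------------
# Forecasting models
# ---------------------------------------------------------------------------

DEFAULT_SIGNATURE_MENU: tuple[str, ...] = (
    "S(t) -> S(t+1)",
    "dS(t) -> dS(t+1)",
    "S(t)&dS(t) -> dS(t+1)",
    "S(t)&dS(t)&d2S(t) -> d2S(t+1)",
)


@dataclass(frozen=True)
class LflfConfig:
    """Tunables of the forecaster.

    ``n_components``: fuzzy-partition size for the trend-cycle (None means
    ceil(T/7), one node per ~7 samples); ``shape``: basic-function family;
    ``ar_order``: seasonal AR order (None selects 1..ar_order_max on a
    holdout); ``signature_menu``: candidate rule signatures for model
    selection.
    """

    n_components: int | None = None
    shape: str = "triangular"
    ar_order: int | None = None
    ar_order_max: int = 5
    signature_menu: tuple[str, ...] = DEFAULT_SIGNATURE_MENU


@dataclass
class ForecastModel:
    """A fitted predictor: rule base + partition + seasonal AR model."""

    signature: RuleSignature
    description: LinguisticDescription
    decomposition: Decomposition
    seasonal_model: SeasonalAR
    smape_validation: float | None = None

    @property
    def partition(self) -> FuzzyPartition:
        return self.decomposition.components.partition


@dataclass
class ForecastResult:
    """Forecast values with their additive trend and seasonal parts."""

    values: np.ndarray
    trend: np.ndarray
    seasonal: np.ndarray

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def __len__(self) -> int:
        return len(self.values)


def fit_forecaster(
    series, signature: RuleSignature | str, config: LflfConfig | None = None
) -> ForecastModel:
    """Decompose a series, induce rules for the signature, fit the seasonal AR."""
    if config is None:
        config = LflfConfig()
    if isinstance(signature, str):
        signature = RuleSignature.parse(signature)
    series = np.asarray(series, dtype=float)
    dec = decompose(series, n=config.n_components, shape=config.shape)
    cs = component_differences(dec.components.values)
    description = generate_rules(cs, signature)
    seasonal_model = fit_seasonal(dec.seasonal, order=config.ar_order, max_order=config.ar_order_max)
    return ForecastModel(
        signature=signature,
        description=description,
        decomposition=dec,
        seasonal_model=seasonal_model,
    )


def _apply_consequent(X: list[float], consequent_var: str, value: float) -> float:
    base, _ = _parse_var(consequent_var)
    if base == "S":
        return value
    if base == "dS":
        return X[-1] + value
    return 2.0 * X[-1] - X[-2] + value  # d2S: next difference = last difference + value


def _extended_trend(
    nodes: np.ndarray, comps: np.ndarray, shape: str, t: np.ndarray
) -> np.ndarray:
    """Inverse transform over an extended uniform partition.

    For triangular basic functions the inverse transform is exactly the
    piecewise-linear interpolant through (c_i, F_i); for raised cosine it
    is the cosine-blended interpolant.
    """
    if shape == "triangular":
        return np.interp(t, nodes, comps)
    h = nodes[1] - nodes[0]
    idx = np.clip(np.searchsorted(nodes, t, side="right") - 1, 0, len(nodes) - 2)
    d = (t - nodes[idx]) / h
    w = 0.5 * (1.0 + np.cos(np.pi * d))
    return w * comps[idx] + (1.0 - w) * comps[idx + 1]


def forecast(model: ForecastModel, horizon: int, series=None) -> ForecastResult:
    """Forecast the next ``horizon`` samples past the end of the fitted series.

    Future trend-cycle components are produced by iterated rule deduction,
    the partition is extended with equidistant nodes to cover the horizon,
    and the seasonal residual is extrapolated by the AR model.  The
    returned values are the elementwise sum of the two parts.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    dec = model.decomposition
    nodes = model.partition.nodes
    h = float(nodes[1] - nodes[0])
    T = len(dec.original)
    X = list(dec.components.values)
    n_extra = max(1, math.ceil(horizon / h) + 1)
    for _ in range(n_extra):
        i = len(X) - 1
        current = {v: _var_value(v, np.asarray(X), i) for v in model.signature.antecedents}
        val = deduce(model.description, current)
        X.append(_apply_consequent(X, model.signature.consequent, val))
    nodes_ext = np.concatenate([nodes, nodes[-1] + h * np.arange(1, n_extra + 1)])
    t_future = np.arange(T + 1, T + horizon + 1, dtype=float)
    trend = _extended_trend(nodes_ext, np.asarray(X), model.partition.shape, t_future)
    seasonal = model.seasonal_model.forecast(dec.seasonal, horizon)
    return ForecastResult(values=trend + seasonal, trend=trend, seasonal=seasonal)


def smape(actual, forecast) -> float:
    """SMAPE in percent: (100/T) * sum |F-A| / ((|A|+|F|)/2).

    Pairs where both values are exactly zero contribute nothing.
    """
    A = np.asarray(actual, dtype=float)
    F = np.asarray(np.asarray(forecast), dtype=float)
    if A.shape != F.shape or A.ndim != 1 or len(A) == 0:
        raise ValueError(f"need equal-length nonempty vectors, got {A.shape} and {F.shape}")
    den = (np.abs(A) + np.abs(F)) / 2.0
    terms = np.zeros(len(A))
    nz = den > 0
    terms[nz] = np.abs(F[nz] - A[nz]) / den[nz]
    return float(100.0 * terms.mean())


def select_best_predictor(
    train,
    validation,
    signature_menu: Sequence[RuleSignature | str] | None = None,
    config: LflfConfig | None = None,
) -> ForecastModel:
    """Fit one model per signature on ``train`` and keep the validation-SMAPE minimizer.

    Ties go to the signature with fewer antecedent variables, then to menu
    order.  The winning model carries its validation SMAPE.
    """
    if config is None:
        config = LflfConfig()
    if signature_menu is None:
        signature_menu = config.signature_menu
    signature_menu = list(signature_menu)
    if not signature_menu:
        raise ValueError("signature menu must be nonempty")
    validation = np.asarray(validation, dtype=float)
    if len(validation) == 0:
        raise ValueError("validation block must be nonempty")
    best: ForecastModel | None = None
    best_key: tuple[float, int, int] | None = None
    failures: list[str] = []
    for pos, sig in enumerate(signature_menu):
        try:
            model = fit_forecaster(train, sig, config)
            fc = forecast(model, len(validation))
            score = smape(validation, fc.values)
        except (ValueError, np.linalg.LinAlgError) as exc:
            failures.append(f"{sig if isinstance(sig, str) else sig.render()}: {exc}")
            continue
        model.smape_validation = score
        key = (score, len(model.signature.antecedents), pos)
        if best_key is None or key < best_key:
            best, best_key = model, key
    if best is None:
        raise ValueError("every candidate signature failed to fit: " + "; ".join(failures))
    return best


@dataclass
class SmapeClassification:
    verdict: str  # "healthy" | "sick"
    smape_healthy: float
    smape_sick: float


def verdict_from_smape(smape_healthy: float, smape_sick: float) -> str:
    """Healthy iff SMAPE(healthy+tested) is strictly smaller; otherwise sick."""
    return "healthy" if smape_healthy < smape_sick else "sick"


def classify_by_smape(
    healthy_learning,
    sick_learning,
    tested,
    config: LflfConfig | None = None,
) -> SmapeClassification:
    """SMAPE-comparison classifier over concatenated learning + tested series.

    The tested block is appended to each learning series as its validation
    part; the best predictor fitted on each learning block is scored by
    SMAPE on the tested block, and the smaller SMAPE names the class
    (ties fall to sick).
    """
    healthy_learning = np.asarray(healthy_learning, dtype=float)
    sick_learning = np.asarray(sick_learning, dtype=float)
    tested = np.asarray(tested, dtype=float)
    for name, arr in (("healthy_learning", healthy_learning), ("sick_learning", sick_learning), ("tested", tested)):
        if arr.ndim != 1 or len(arr) == 0:
            raise ValueError(f"{name} must be a nonempty 1-D series")
    model_h = select_best_predictor(healthy_learning, tested, config=config)
    model_s = select_best_predictor(sick_learning, tested, config=config)
    sh = float(model_h.smape_validation)
    ss = float(model_s.smape_validation)
    return SmapeClassification(verdict=verdict_from_smape(sh, ss), smape_healthy=sh, smape_sick=ss)
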