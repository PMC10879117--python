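"""Chain Bayesian-network model of editing-outcome proportions.

Editing at each editable position is Bernoulli with marginal m_i (the
per-position efficiency, typically supplied by the efficiency model);
dependence between adjacent editable positions is summarized by an odds
ratio c = p11*p00 / (p01*p10).  The joint distribution over all
positions factorizes as a chain, P(X1..Xn) = P(X1) prod P(Xi | Xi-1),
with each conditional derived from the 2x2 joint reconstructed from the
two marginals and c (the Plackett-copula inversion).  Distant-position
dependence is transmitted through the chain; the mutual-information
audit quantifies how much dependence that simplification misses.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .quant import OutcomeAllele, OutcomeDistribution, pattern_string
from .sites import SiteError

logger = logging.getLogger(__name__)

EPS_MARGIN = 1e-6
MAX_ENUM_POSITIONS = 12


# ---------------------------------------------------------------------------
# 2x2 joint from marginals + odds ratio


@dataclass(frozen=True)
class Joint2x2:
    """Joint distribution of an ordered pair of editable positions."""

    p11: float
    p10: float
    p01: float
    p00: float

    def as_array(self) -> np.ndarray:
        return np.array([[self.p00, self.p01], [self.p10, self.p11]])

    @property
    def odds_ratio(self) -> float:
        return (self.p11 * self.p00) / (self.p01 * self.p10)


def joint_from_margins_or(p: float, q: float, c: float) -> Joint2x2:
    """Reconstruct the 2x2 joint from margins P(X=1)=p, P(Y=1)=q and
    odds ratio c.

    For c != 1, p11 is the smaller root of the quadratic
    (c-1) p11^2 - S p11 + c p q = 0 with S = 1 + (p+q)(c-1) -- the only
    root inside the Frechet bounds max(0, p+q-1) <= p11 <= min(p, q).
    """
    if not (0 < p < 1 and 0 < q < 1):
        raise SiteError(f"marginals must lie in (0,1), got p={p}, q={q}")
    if c <= 0:
        raise SiteError(f"odds ratio must be positive, got c={c}")
    if c == 1.0:
        p11 = p * q
    else:
        s = 1.0 + (p + q) * (c - 1.0)
        disc = s * s - 4.0 * c * (c - 1.0) * p * q
        p11 = (s - math.sqrt(max(disc, 0.0))) / (2.0 * (c - 1.0))
    lo = max(0.0, p + q - 1.0)
    hi = min(p, q)
    p11 = min(max(p11, lo), hi)
    return Joint2x2(
        p11=p11, p10=p - p11, p01=q - p11, p00=1.0 - p - q + p11
    )


# ---------------------------------------------------------------------------
# chain model


@dataclass
class ChainProportionModel:
    """Editable positions (ascending), marginals, adjacent odds ratios."""

    positions: tuple[int, ...]
    marginals: np.ndarray                 # m_i = P(X_i = 1)
    odds_ratios: np.ndarray               # c_i for (x_i, x_{i+1}); length n-1
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.positions = tuple(int(p) for p in self.positions)
        self.marginals = np.clip(
            np.asarray(self.marginals, float), EPS_MARGIN, 1 - EPS_MARGIN
        )
        self.odds_ratios = np.asarray(self.odds_ratios, float)
        n = len(self.positions)
        if self.marginals.shape != (n,):
            raise SiteError("marginals length must match positions")
        if n > 1 and self.odds_ratios.shape != (n - 1,):
            raise SiteError("need one odds ratio per adjacent pair")
        if n > 1 and np.any(self.odds_ratios <= 0):
            raise SiteError("odds ratios must be positive")

    @property
    def n(self) -> int:
        return len(self.positions)


def chain_joint(model: ChainProportionModel, pattern: Sequence[int]) -> float:
    """Probability of one binary edit pattern under the chain.

    P = P(X1=b1) * prod_i P(Xi=bi | X(i-1)=b(i-1)), with each
    conditional taken from the 2x2 joint of the adjacent pair.
    """
    b = [int(v) for v in pattern]
    if len(b) != model.n:
        raise SiteError(f"pattern length {len(b)} != {model.n} editable positions")
    m = model.marginals
    prob = m[0] if b[0] else 1.0 - m[0]
    for i in range(1, model.n):
        j = joint_from_margins_or(m[i - 1], m[i], model.odds_ratios[i - 1])
        table = {
            (1, 1): j.p11, (1, 0): j.p10, (0, 1): j.p01, (0, 0): j.p00,
        }
        prev_margin = m[i - 1] if b[i - 1] else 1.0 - m[i - 1]
        prob *= table[(b[i - 1], b[i])] / prev_margin
    return prob


def predict_proportions(
    model: ChainProportionModel,
    site_id: str = "",
    remove_wildtype: bool = False,
    proportion_threshold: Optional[float] = None,
) -> OutcomeDistribution:
    """Enumerate all 2^n edit patterns and score them under the chain.

    With ``remove_wildtype`` / ``proportion_threshold``, mirrors the
    observed-distribution processing (wild type dropped, alleles at or
    below the threshold dropped, renormalized) so predictions are
    directly comparable with collapsed observed outcomes.
    """
    if model.n > MAX_ENUM_POSITIONS:
        raise SiteError(
            f"{model.n} editable positions exceed the enumeration limit "
            f"{MAX_ENUM_POSITIONS}; restrict the window"
        )
    probs: dict[tuple[int, ...], float] = {}
    for bits in itertools.product((0, 1), repeat=model.n):
        probs[bits] = chain_joint(model, bits)
    if remove_wildtype:
        probs.pop((0,) * model.n, None)
    z = sum(probs.values())
    if z <= 0:
        return OutcomeDistribution(site_id=site_id, alleles=[], provenance="predicted")
    props = {k: v / z for k, v in probs.items()}
    if proportion_threshold is not None:
        props = {k: v for k, v in props.items() if v > proportion_threshold}
        z2 = sum(props.values())
        props = {k: v / z2 for k, v in props.items()}
    alleles = [
        OutcomeAllele(
            pattern=pattern_string(
                p for p, bit in zip(model.positions, bits) if bit
            ),
            proportion=prop,
        )
        for bits, prop in sorted(props.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return OutcomeDistribution(site_id=site_id, alleles=alleles, provenance="predicted")


# ---------------------------------------------------------------------------
# odds-ratio estimation from observed outcomes


def _pair_cells(
    dist_by_pattern: Mapping[str, float], pos_a: int, pos_b: int
) -> np.ndarray:
    """Proportion-weighted 2x2 cell mass [ [n00, n01], [n10, n11] ]."""
    cells = np.zeros((2, 2))
    for pattern, prop in dist_by_pattern.items():
        a = 1 if pattern[pos_a - 1] == "1" else 0
        b = 1 if pattern[pos_b - 1] == "1" else 0
        cells[a, b] += prop
    return cells


def estimate_adjacent_or(
    outcomes: Sequence[OutcomeDistribution] | Mapping[str, Mapping[str, float]],
    positions_by_site: Mapping[str, Sequence[int]],
    weights: Optional[Mapping[str, float]] = None,
    pseudocount: float = 0.5,
) -> dict[tuple[int, int], float]:
    """Estimate c for each adjacent editable-position pair.

    2x2 cell mass is pooled over sites covering the pair --
    proportion-weighted, scaled by the per-site weight (read depth when
    known, 1 otherwise) -- then the pseudocount is added to every cell
    and c = p11*p00 / (p01*p10).  Pairs never observed get c = 1 with a
    warning.
    """
    if isinstance(outcomes, Mapping):
        items = list(outcomes.items())
    else:
        items = [(d.site_id, d.by_pattern()) for d in outcomes if not d.empty]
    pooled: dict[tuple[int, int], np.ndarray] = {}
    for site_id, by_pattern in items:
        pos = sorted(positions_by_site.get(site_id, ()))
        if len(pos) < 2 or not by_pattern:
            continue
        w = float(weights.get(site_id, 1.0)) if weights else 1.0
        for a, b in zip(pos[:-1], pos[1:]):
            key = (a, b)
            pooled.setdefault(key, np.zeros((2, 2)))
            pooled[key] += w * _pair_cells(by_pattern, a, b)
    out: dict[tuple[int, int], float] = {}
    all_pairs = {
        (a, b)
        for pos in map(sorted, positions_by_site.values())
        for a, b in zip(pos[:-1], pos[1:])
    }
    for pair in sorted(all_pairs):
        if pair not in pooled or pooled[pair].sum() == 0:
            logger.warning("pair %s never observed; using c = 1", pair)
            out[pair] = 1.0
            continue
        cells = pooled[pair] + pseudocount
        out[pair] = float(
            (cells[1, 1] * cells[0, 0]) / (cells[0, 1] * cells[1, 0])
        )
    return out


# ---------------------------------------------------------------------------
# form classification


@dataclass
class FormLabels:
    """All-/Edited-/Max-form labels over an outcome distribution."""

    forms: dict = field(default_factory=dict)  # pattern -> label
    max_form: Optional[str] = None
    has_edited: bool = False


def classify_forms(dist: OutcomeDistribution) -> FormLabels:
    """Label each outcome; pick the Max-form among Edited-forms.

    Edited-forms carry >= 1 intended transition.  The Max-form is the
    Edited-form with the largest proportion; ties break deterministically
    toward fewer edited bases, then the leftmost edited position, then
    lexicographic pattern order.
    """
    labels = FormLabels()
    best_key = None
    best = None
    for a in dist.alleles:
        if a.n_edited == 0:
            labels.forms[a.pattern] = "wild-type" if not a.side else "other"
            continue
        labels.forms[a.pattern] = "Edited-form"
        labels.has_edited = True
        first = a.edited_positions[0]
        key = (-a.proportion, a.n_edited, first, a.pattern)
        if best_key is None or key < best_key:
            best_key, best = key, a.pattern
    labels.max_form = best
    return labels


# ---------------------------------------------------------------------------
# mutual-information audit


def _mi_bits(pxy: np.ndarray) -> float:
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    mi = 0.0
    for a in (0, 1):
        for b in (0, 1):
            if pxy[a, b] > 0 and px[a] > 0 and py[b] > 0:
                mi += pxy[a, b] * math.log2(pxy[a, b] / (px[a] * py[b]))
    return mi


def mutual_information_audit(
    dist_by_pattern: Mapping[str, float], positions: Sequence[int]
) -> dict:
    """Pairwise MI (bits) between editable positions, plus the
    conditional MI of each distant pair given the intermediate position.

    A small conditional MI for distant pairs supports the chain
    simplification: their dependence is carried through the adjacent
    links.
    """
    positions = sorted(positions)
    pairwise: dict[tuple[int, int], float] = {}
    for a, b in itertools.combinations(positions, 2):
        pairwise[(a, b)] = _mi_bits(_pair_cells(dist_by_pattern, a, b))
    conditional: dict[tuple[int, int, int], float] = {}
    for i in range(len(positions) - 2):
        a, mid, b = positions[i], positions[i + 1], positions[i + 2]
        # p(xa, xmid, xb)
        p3 = np.zeros((2, 2, 2))
        for pattern, prop in dist_by_pattern.items():
            ia = 1 if pattern[a - 1] == "1" else 0
            im = 1 if pattern[mid - 1] == "1" else 0
            ib = 1 if pattern[b - 1] == "1" else 0
            p3[ia, im, ib] += prop
        cmi = 0.0
        for m in (0, 1):
            pm = p3[:, m, :].sum()
            if pm > 0:
                cmi += pm * _mi_bits(p3[:, m, :] / pm)
        conditional[(a, mid, b)] = cmi
    adjacent = {
        k: v for k, v in pairwise.items()
        if positions.index(k[1]) - positions.index(k[0]) == 1
    }
    distant = {k: v for k, v in pairwise.items() if k not in adjacent}
    return {
        "pairwise": pairwise,
        "adjacent": adjacent,
        "distant": distant,
        "conditional_given_intermediate": conditional,
    }
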