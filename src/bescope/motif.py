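"""Sequence-motif model: fractional logistic regression of per-base
editing efficiency on the 7-nt context around each window target base
(3 nt upstream + target + 3 nt downstream).

Efficiencies are fractional responses in [0, 1], so the model is fit as
a fractional logit (binomial family with logit link, quasi-likelihood
via IRLS) rather than a binary classifier.  Responses at exactly 0 or 1
are nudged by a small epsilon so the logit stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .quant import SiteEditingSummary
from .sites import RunConfig, SiteError, TargetSite, window_positions
from .stats import pearson_with_ci

EPS = 1e-6
BASES = "ACGT"
FLANK = 3


@dataclass(frozen=True)
class ContextExample:
    """One window target base with its 7-nt context and efficiency."""

    site_id: str
    position: int          # protospacer position 1-20
    context7: str
    efficiency: float

    def __post_init__(self) -> None:
        if len(self.context7) != 7:
            raise SiteError(f"{self.site_id}: context7 must have length 7")


def build_examples(
    sites: Sequence[TargetSite],
    summaries: Sequence[SiteEditingSummary],
    cfg: RunConfig,
    seed: Optional[int] = None,
    split: float = 0.7,
) -> tuple[list[ContextExample], list[ContextExample]]:
    """One example per window target base; deterministic 70/30 split.

    The split is by a seeded shuffle of the examples (seed defaults to
    ``cfg.seed``).
    """
    by_id = {s.site_id: s for s in summaries}
    examples = []
    for site in sites:
        summ = by_id.get(site.site_id)
        if summ is None:
            continue
        for p in site.target_positions(cfg.window):
            eff = summ.per_position_efficiency[p - 1]
            if eff is None:
                continue
            i = 10 + p - 1  # context40 index of position p
            ctx = site.context40[i - FLANK : i + FLANK + 1]
            examples.append(
                ContextExample(site_id=site.site_id, position=p, context7=ctx,
                               efficiency=float(eff))
            )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    order = rng.permutation(len(examples))
    n_train = int(round(split * len(examples)))
    train = [examples[i] for i in order[:n_train]]
    test = [examples[i] for i in order[n_train:]]
    return train, test


def encode_context(context7: str, editor: str) -> np.ndarray:
    """24-length one-hot vector: 6 flanking positions x 4 bases.

    The center base is constant for an editor (A for ABE, C for CBE) and
    is excluded; a wrong center base is an error.
    """
    from .sites import TARGET_BASE

    if len(context7) != 7:
        raise SiteError("context7 must have length 7")
    if context7[FLANK] != TARGET_BASE[editor]:
        raise SiteError(
            f"center base {context7[FLANK]} invalid for {editor} "
            f"(expected {TARGET_BASE[editor]})"
        )
    vec = np.zeros(24)
    flanks = context7[:FLANK] + context7[FLANK + 1 :]
    for i, base in enumerate(flanks):
        vec[i * 4 + BASES.index(base)] = 1.0
    return vec


@dataclass
class MotifModelResult:
    params: np.ndarray           # intercept + 24 flank coefficients
    test_r: float
    variance_explained: float    # square of test R
    n_train: int
    n_test: int
    predictions: np.ndarray
    observed: np.ndarray


class MotifModel:
    """Fractional logit on one-hot flank features."""

    def __init__(self, params: np.ndarray, editor: str):
        self.params = params
        self.editor = editor

    def predict(self, examples: Sequence[ContextExample]) -> np.ndarray:
        X = np.array([encode_context(e.context7, self.editor) for e in examples])
        X = sm.add_constant(X, has_constant="add")
        eta = X @ self.params
        return 1.0 / (1.0 + np.exp(-eta))


def fit_and_evaluate(
    train: Sequence[ContextExample],
    test: Sequence[ContextExample],
    editor: str,
    nonzero_only: bool = False,
) -> tuple[MotifModel, MotifModelResult]:
    """Fit the fractional logit on train, report Pearson R on test.

    ``nonzero_only`` restricts evaluation to examples with non-zero
    observed efficiency (used when a model trained on one dataset is
    applied across datasets).
    """
    X = np.array([encode_context(e.context7, editor) for e in train])
    y = np.clip(
        np.array([e.efficiency for e in train]), EPS, 1 - EPS
    )
    X = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    fit = model.fit(maxiter=500, tol=1e-6)
    if not fit.converged:
        # IRLS can enter a shallow limit cycle when the likelihood is
        # nearly flat (many near-zero responses); a warm restart, then a
        # quasi-Newton pass, settles on the same optimum
        fit = model.fit(start_params=fit.params, maxiter=100, tol=1e-6)
    if not fit.converged:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alt = model.fit(method="lbfgs", maxiter=2000, disp=0)
        if alt.deviance <= fit.deviance + 1e-6:
            fit = alt
        else:
            raise SiteError("fractional logit did not converge "
                            f"(deviance {fit.deviance:.3g})")
    m = MotifModel(params=np.asarray(fit.params), editor=editor)

    eval_examples = list(test)
    if nonzero_only:
        eval_examples = [e for e in eval_examples if e.efficiency > 0]
    preds = m.predict(eval_examples)
    obs = np.array([e.efficiency for e in eval_examples])
    r = pearson_with_ci(preds, obs).r if len(obs) >= 3 else float("nan")
    return m, MotifModelResult(
        params=m.params,
        test_r=float(r),
        variance_explained=float(r) ** 2,
        n_train=len(train),
        n_test=len(eval_examples),
        predictions=preds,
        observed=obs,
    )


def position_weight_matrix(model: MotifModel) -> np.ndarray:
    """6x4 matrix of flank coefficients (motif-logo export)."""
    return model.params[1:].reshape(6, 4)
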