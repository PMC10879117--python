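"""Per-position editing-efficiency model: input encoding, the shuffled
stratified training protocol, prediction and evaluation.

The model maps a 40-nt target context -- one-hot sequence channels plus
optional endogenous-factor channels -- to a 20-long vector of predicted
editing probabilities, one per protospacer position.  The sequence-only
channel set gives the "seq" model; adding factor channels gives the
"endo" model (H3K27ac only for ABE, every factor for CBE by default,
following which factors measurably modulate each editor).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .endo import EndoAnnotation
from .nn import ConvEfficiencyNet, NetConfig
from .quant import SiteEditingSummary
from .sites import SiteError, TargetSite
from .stats import pearson_with_ci

logger = logging.getLogger(__name__)

BASES = "ACGT"

ALL_FACTOR_CHANNELS = (
    "expression", "PolII", "CTCF", "DHS",
    "H3K4me1", "H3K4me3", "H3K27ac", "H3K36me3",
    "methylation", "CRE",
)

#: default endo-model channel sets per editor
DEFAULT_ENDO_CHANNELS = {
    "ABE": ("H3K27ac",),
    "CBE": ALL_FACTOR_CHANNELS,
}


# ---------------------------------------------------------------------------
# encoding


def encode_input(
    site: TargetSite,
    annotation: Optional[EndoAnnotation],
    channels: Sequence[str] = (),
) -> np.ndarray:
    """40 x (4 + k) input matrix for one site.

    Sequence is one-hot over ACGT.  Each factor channel broadcasts its
    normalized per-site value down the 40-nt axis, except
    ``methylation`` which is laid per-base along covered protospacer
    positions (0 elsewhere).
    """
    k = len(channels)
    mat = np.zeros((40, 4 + k))
    for i, base in enumerate(site.context40):
        mat[i, BASES.index(base)] = 1.0
    for j, ch in enumerate(channels):
        if annotation is None:
            raise SiteError(f"{site.site_id}: no annotation but channel {ch!r} requested")
        if ch == "methylation" and annotation.per_base_methylation:
            for p, beta in annotation.per_base_methylation.items():
                mat[10 + p - 1, 4 + j] = beta
        else:
            if ch not in annotation.continuous:
                raise SiteError(f"{site.site_id}: missing factor channel {ch!r}")
            mat[:, 4 + j] = annotation.continuous[ch]
    return mat


def build_dataset(
    sites: Sequence[TargetSite],
    summaries: Sequence[SiteEditingSummary],
    annotations: Optional[Mapping[str, EndoAnnotation]] = None,
    channels: Sequence[str] = (),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack (X, Y, mask) over sites with observed per-position labels.

    The mask marks target-base positions (where the per-position
    efficiency is defined); the loss and evaluation ignore everything
    else.
    """
    by_id = {s.site_id: s for s in summaries}
    xs, ys, ms = [], [], []
    for site in sites:
        summ = by_id.get(site.site_id)
        if summ is None:
            continue
        ann = annotations.get(site.site_id) if annotations else None
        xs.append(encode_input(site, ann, channels))
        y = np.zeros(20)
        m = np.zeros(20)
        for i, eff in enumerate(summ.per_position_efficiency):
            if eff is not None:
                y[i] = eff
                m[i] = 1.0
        ys.append(y)
        ms.append(m)
    return np.array(xs), np.array(ys), np.array(ms)


# ---------------------------------------------------------------------------
# model container


@dataclass
class EfficiencyModel:
    """A trained per-position efficiency predictor."""

    editor: str
    channels: tuple[str, ...]
    net: ConvEfficiencyNet

    def predict_matrix(self, x: np.ndarray) -> np.ndarray:
        return self.net.predict(x)

    def predict_sites(
        self,
        sites: Sequence[TargetSite],
        annotations: Optional[Mapping[str, EndoAnnotation]] = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-site 20-vectors in [0, 1] plus a target-base mask.

        Positions whose reference base is not the editor's target base
        are still reported but flagged 0 in the mask.
        """
        x = np.array([
            encode_input(s, annotations.get(s.site_id) if annotations else None,
                         self.channels)
            for s in sites
        ])
        preds = self.net.predict(x)
        mask = np.array([
            [1.0 if s.base_at(p) == s.target_base else 0.0 for p in range(1, 21)]
            for s in sites
        ])
        return preds, mask


def save_model(model: EfficiencyModel, path: str | Path) -> None:
    """Self-describing JSON container: spec + weights."""
    cfg = model.net.config
    payload = {
        "editor": model.editor,
        "channels": list(model.channels),
        "net_config": {
            "in_channels": cfg.in_channels,
            "length": cfg.length,
            "out_length": cfg.out_length,
            "kernel_widths": list(cfg.kernel_widths),
            "n_filters": cfg.n_filters,
        },
        "weights": {k: v.tolist() for k, v in model.net.state_dict().items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> EfficiencyModel:
    payload = json.loads(Path(path).read_text())
    nc = payload["net_config"]
    config = NetConfig(
        in_channels=nc["in_channels"],
        length=nc["length"],
        out_length=nc["out_length"],
        kernel_widths=tuple(nc["kernel_widths"]),
        n_filters=nc["n_filters"],
    )
    net = ConvEfficiencyNet(config)
    net.load_state_dict(payload["weights"])
    return EfficiencyModel(
        editor=payload["editor"], channels=tuple(payload["channels"]), net=net
    )


# ---------------------------------------------------------------------------
# training protocol


@dataclass
class TrainingProtocol:
    """Shuffled stratified split protocol: 80/20 train/test repeated
    over independent shuffles, 20% per-epoch validation inside train."""

    n_shuffles: int = 6
    test_fraction: float = 0.2
    validation_fraction: float = 0.2
    seed: int = 0


@dataclass
class ShuffleResult:
    shuffle: int
    seed: int
    test_r: float
    per_position_r: dict
    n_train: int
    n_test: int
    test_indices: np.ndarray


@dataclass
class TrainResult:
    models: list
    shuffles: list
    pooled_test_r: float


def _stratified_split(
    strata: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for value in np.unique(strata):
        idx = np.flatnonzero(strata == value)
        rng.shuffle(idx)
        n_test = int(round(test_fraction * idx.size))
        if n_test == 0 or n_test == idx.size:
            logger.warning("empty stratum side for stratum %r; unstratified fallback", value)
            return _stratified_split(np.zeros_like(strata), test_fraction, rng)
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def masked_pearson(pred: np.ndarray, obs: np.ndarray, mask: np.ndarray) -> float:
    sel = mask > 0
    if sel.sum() < 3:
        return float("nan")
    return float(np.corrcoef(pred[sel], obs[sel])[0, 1])


def train(
    x: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    editor: str,
    channels: Sequence[str] = (),
    strata: Optional[np.ndarray] = None,
    protocol: Optional[TrainingProtocol] = None,
    net_config: Optional[NetConfig] = None,
) -> TrainResult:
    """Run the full shuffled training protocol.

    ``strata`` is the stratification key (presence/absence of any
    endogenous-factor flag); each shuffle draws an independent seeded
    80/20 split, trains with per-epoch validation and early stopping,
    and reports pooled and per-position test Pearson R.
    """
    protocol = protocol or TrainingProtocol()
    if net_config is None:
        net_config = NetConfig(in_channels=x.shape[2])
    if net_config.in_channels != x.shape[2]:
        raise SiteError(
            f"channel mismatch: input has {x.shape[2]} channels, "
            f"net expects {net_config.in_channels}"
        )
    if x.shape[0] < 10:
        raise SiteError("need at least 10 sites to train")
    if strata is None:
        strata = np.zeros(x.shape[0], dtype=int)
    models, shuffles = [], []
    pooled_pred, pooled_obs = [], []
    for k in range(protocol.n_shuffles):
        seed = protocol.seed * 1009 + k
        rng = np.random.default_rng(seed)
        tr, te = _stratified_split(np.asarray(strata), protocol.test_fraction, rng)
        net = ConvEfficiencyNet(net_config, seed=seed)
        net.config.validation_fraction = protocol.validation_fraction
        net.fit(x[tr], y[tr], mask[tr], seed=seed)
        model = EfficiencyModel(editor=editor, channels=tuple(channels), net=net)
        pred = net.predict(x[te])
        r = masked_pearson(pred, y[te], mask[te])
        per_pos = {}
        for p in range(20):
            sel = mask[te][:, p] > 0
            if sel.sum() >= 3 and np.std(y[te][sel, p]) > 0:
                per_pos[p + 1] = float(np.corrcoef(pred[sel, p], y[te][sel, p])[0, 1])
        models.append(model)
        shuffles.append(
            ShuffleResult(
                shuffle=k, seed=seed, test_r=r, per_position_r=per_pos,
                n_train=tr.size, n_test=te.size, test_indices=te,
            )
        )
        sel = mask[te] > 0
        pooled_pred.append(pred[sel])
        pooled_obs.append(y[te][sel])
    pooled_r = float(
        np.corrcoef(np.concatenate(pooled_pred), np.concatenate(pooled_obs))[0, 1]
    )
    return TrainResult(models=models, shuffles=shuffles, pooled_test_r=pooled_r)


# ---------------------------------------------------------------------------
# evaluation


def evaluate(
    pred: np.ndarray,
    obs: np.ndarray,
    mask: np.ndarray,
    groups: Optional[Mapping[str, np.ndarray]] = None,
):
    """Pooled Pearson R with Fisher-z CI, plus per-group correlations.

    ``groups`` maps a label to a boolean site selector (e.g. a motif or
    factor subgroup); each group's R is computed over its masked
    positions.
    """
    sel = mask > 0
    pooled = pearson_with_ci(pred[sel], obs[sel])
    out = {"pooled": pooled}
    if groups:
        for label, g in groups.items():
            gsel = sel & np.asarray(g, bool)[:, None]
            if gsel.sum() >= 3:
                out[label] = pearson_with_ci(pred[gsel], obs[gsel])
    return out
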