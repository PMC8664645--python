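"""Linear-Gaussian simulator of a hierarchical visual system.

The simulator produces trial datasets with the structure of a generic object
decoding experiment (disjoint train/test category sets, repeated test
presentations, perception and imagery test sessions) from an explicit
generative law in which every region's activity is the sum of

* a private bottom-up stimulus encoding of its preferred feature layer,
* feedforward cross-talk cascading up from the region below,
* top-down mixtures of the higher regions' encoded content, and
* iid Gaussian trial noise.

Because the law is linear-Gaussian, the sign of every distillation effect is
analytically predictable (:func:`expected_effect_sign`) and all downstream
stages can be validated against known ground truth without real fMRI data.

Generative law (per category ``c``, regions ``k = 1..K`` ordered low→high,
layers ``l = 1..L``; region ``k`` prefers layer ``l(k) = ceil(kL/K)``):

perception (``g`` = ``crosstalk_gain``)::

    x̃_k = κ_bu·(E_k·f_{l(k)}(c) + g·U_{k−1→k}·x̃_{k−1})            (feedforward)
    x_k  = x̃_k + κ_td·Σ_{j>k} D_{j→k}·E_j·f_{l(j)}(c) + ε

imagery (stimulus drive removed from all but the top region; lower regions
receive a top-down replay of the recalled feedforward representations)::

    x_K = κ_bu·E_K·f_{l(K)}(c) + ε
    x_k = κ_td·Σ_{j>k} D_{j→k}·x̃_j(c) + ε            (k < K)

All mixing-matrix entries are iid ``N(0, 1/fan_in)`` (sd ``1/√fan_in``), which
keeps per-region variance comparable across depths. The per-hop cascade gain
``g < 1`` makes neighbouring regions share feedforward signal strongly
(variance fraction g² after one hop) while distant regions inherit almost
none of it (g^(2·hops)) — the regime in which removing a distant seed's
prediction strips top-down contamination without destroying the target's own
stimulus signal, whereas removing a neighbour's prediction strips shared
signal. Feature tables contain the exact generating feature values, noise
free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datasets import FeatureTable, TrialDataset, ValidationError

CANONICAL_ROIS = ("V1", "V2", "V3", "V4", "LOC", "FFA", "PPA")


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cortex.

    Defaults mirror the emulated experiment: 7 hierarchically ordered ROIs,
    150 training categories presented 8 times (1,200 training trials, split
    600/600 into train/validation), and 50 disjoint test categories presented
    35 times in the perception session and 10 times in the imagery session.
    """

    n_regions: int = 7
    voxels_per_region: int = 60
    n_train_categories: int = 150
    n_test_categories: int = 50
    train_trials: int = 1200
    test_reps_perception: int = 35
    test_reps_imagery: int = 10
    n_feature_layers: int = 4
    units_per_layer: int = 30
    kappa_bu: float = 1.0   # bottom-up gain
    kappa_td: float = 0.5   # top-down gain
    noise_sd: float = 1.0
    crosstalk_gain: float = 0.6  # per-hop feedforward cascade attenuation
    global_signal_sd: float = 1.0    # trial-wise shared activation amplitude
    global_signal_decay: float = 0.93  # its inter-region correlation per hop
    mode: str = "both"      # which test splits to generate
    rng_seed: int = 0
    subject_id: str = "sim-01"

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValidationError("need at least 2 regions")
        if self.kappa_bu < 0 or self.kappa_td < 0 or self.crosstalk_gain < 0:
            raise ValidationError("gains must be non-negative")
        if self.global_signal_sd < 0 or not 0 <= self.global_signal_decay < 1:
            raise ValidationError(
                "need global_signal_sd >= 0 and 0 <= global_signal_decay < 1"
            )
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.mode not in ("perception", "imagery", "both"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.train_trials % self.n_train_categories:
            raise ValidationError(
                "train_trials must be a multiple of n_train_categories"
            )
        if self.n_feature_layers < 1 or self.n_feature_layers > self.n_regions:
            raise ValidationError("need 1 <= n_feature_layers <= n_regions")

    def preferred_layer(self, region: int) -> int:
        """Preferred feature layer of 1-based region ``region``."""
        if not 1 <= region <= self.n_regions:
            raise ValidationError(f"region {region} out of range")
        return math.ceil(region * self.n_feature_layers / self.n_regions)

    @property
    def roi_names(self) -> list:
        if self.n_regions == len(CANONICAL_ROIS):
            return list(CANONICAL_ROIS)
        return [f"R{k}" for k in range(1, self.n_regions + 1)]

    @property
    def feature_names(self) -> list:
        return [f"layer{l}" for l in range(1, self.n_feature_layers + 1)]


@dataclass
class SimTruth:
    """Ground-truth generative parameters stored with a simulated dataset."""

    encoding: list                      # E_k, (voxels × units), per region
    crosstalk_maps: list                # U_{k→k+1}, (voxels × voxels)
    topdown_maps: dict                  # (j, k) j>k → D_{j→k}
    features: list                      # per layer, (n_categories × units)
    category_ids: np.ndarray            # row order of `features`
    layer_of_region: list               # preferred layer per region (1-based)
    perception_patterns: list = field(default=None)  # noiseless, per region
    imagery_patterns: list = field(default=None)


def _noiseless_patterns(config: SimConfig, truth: SimTruth):
    """Per-category noiseless activity per region, both tasks.

    Returns (perception, imagery) lists of (n_categories × voxels) arrays.
    """
    K = config.n_regions
    F = truth.features
    E = truth.encoding
    ff = []  # x̃_k, feedforward part
    for k in range(K):
        own = config.kappa_bu * F[truth.layer_of_region[k] - 1] @ E[k].T
        if config.crosstalk_gain > 0 and k > 0:
            own = own + config.kappa_bu * config.crosstalk_gain * (
                ff[k - 1] @ truth.crosstalk_maps[k - 1].T
            )
        ff.append(own)
    percept = []
    for k in range(K):
        x = ff[k].copy()
        for j in range(k + 1, K):
            enc_j = F[truth.layer_of_region[j] - 1] @ E[j].T
            x += config.kappa_td * enc_j @ truth.topdown_maps[(j, k)].T
        percept.append(x)
    imagery = []
    for k in range(K):
        if k == K - 1:
            imagery.append(
                config.kappa_bu * F[truth.layer_of_region[k] - 1] @ E[k].T
            )
        else:
            x = np.zeros_like(ff[k])
            for j in range(k + 1, K):
                x += config.kappa_td * ff[j] @ truth.topdown_maps[(j, k)].T
            imagery.append(x)
    return percept, imagery


def generate(config: SimConfig):
    """Draw one synthetic subject.

    Returns ``(TrialDataset, [FeatureTable per layer], SimTruth)``. Identical
    configs (including ``rng_seed``) yield bit-identical outputs.
    """
    rng = np.random.default_rng(config.rng_seed)
    K, V, M = config.n_regions, config.voxels_per_region, config.units_per_layer
    L = config.n_feature_layers
    n_cats = config.n_train_categories + config.n_test_categories
    cat_ids = np.arange(n_cats, dtype=np.int64)
    train_cats = cat_ids[: config.n_train_categories]
    test_cats = cat_ids[config.n_train_categories:]

    features = [rng.standard_normal((n_cats, M)) for _ in range(L)]
    encoding = [rng.normal(0.0, 1.0 / math.sqrt(M), size=(V, M)) for _ in range(K)]
    crosstalk_maps = [
        rng.normal(0.0, 1.0 / math.sqrt(V), size=(V, V)) for _ in range(K - 1)
    ]
    topdown_maps = {
        (j, k): rng.normal(0.0, 1.0 / math.sqrt(V), size=(V, V))
        for k in range(K)
        for j in range(k + 1, K)
    }
    truth = SimTruth(
        encoding=encoding,
        crosstalk_maps=crosstalk_maps,
        topdown_maps=topdown_maps,
        features=features,
        category_ids=cat_ids,
        layer_of_region=[config.preferred_layer(k) for k in range(1, K + 1)],
    )
    percept, imagery = _noiseless_patterns(config, truth)
    truth.perception_patterns = percept
    truth.imagery_patterns = imagery

    # Trial bookkeeping: training categories repeated equally then shuffled;
    # first half tagged train, second half validation.
    reps = config.train_trials // config.n_train_categories
    train_order = rng.permutation(np.repeat(train_cats, reps))
    half = config.train_trials // 2
    rows = [(c, "train") for c in train_order[:half]]
    rows += [(c, "validation") for c in train_order[half:]]
    if config.mode in ("perception", "both"):
        order = rng.permutation(np.repeat(test_cats, config.test_reps_perception))
        rows += [(c, "test_perception") for c in order]
    if config.mode in ("imagery", "both"):
        order = rng.permutation(np.repeat(test_cats, config.test_reps_imagery))
        rows += [(c, "test_imagery") for c in order]

    trial_category = np.array([c for c, _ in rows], dtype=np.int64)
    trial_split = np.array([s for _, s in rows])
    trial_run = np.arange(len(rows)) // 50  # 50-trial runs, bookkeeping only

    pattern = {
        split: np.hstack(pats)
        for split, pats in (
            ("perception", percept),
            ("imagery", imagery),
        )
    }
    activity = np.empty((len(rows), K * V))
    for i, (cat, split) in enumerate(rows):
        task = "imagery" if split == "test_imagery" else "perception"
        activity[i] = pattern[task][cat]
    activity += rng.normal(0.0, config.noise_sd, size=activity.shape)

    # trial-wise global activation shared along the pathway: an AR(1) chain
    # across regions (correlation `global_signal_decay` per hop) added
    # uniformly to each region's voxels; carries no category information but
    # produces the strong-nearby / weak-distant trial connectivity of real
    # task fMRI.
    if config.global_signal_sd > 0:
        phi = config.global_signal_decay
        s = config.global_signal_sd
        m = np.empty((len(rows), K))
        m[:, 0] = rng.normal(0.0, s, size=len(rows))
        for k in range(1, K):
            m[:, k] = phi * m[:, k - 1] + math.sqrt(1 - phi**2) * rng.normal(
                0.0, s, size=len(rows)
            )
        activity += np.repeat(m, V, axis=1)

    voxel_roi = np.repeat(config.roi_names, V)
    dataset = TrialDataset(
        subject_id=config.subject_id,
        activity=activity,
        trial_category=trial_category,
        trial_split=trial_split,
        trial_run=trial_run,
        voxel_roi=voxel_roi,
    )
    tables = [
        FeatureTable(
            feature_name=f"layer{l + 1}",
            values=features[l],
            category_ids=cat_ids,
            unit_ids=[f"u{u}" for u in range(M)],
        )
        for l in range(L)
    ]
    return dataset, tables, truth


def expected_effect_sign(
    config: SimConfig,
    seed_region: int,
    target_region: int,
    feature_layer: int,
    task: Optional[str] = None,
) -> str:
    """Analytically expected sign of a distillation effect.

    Qualitative rule set derived from the generative law. Perception: a seed
    that encodes the decoded layer itself (or inherits it through one
    feedforward hop) is a conduit of that feature's information, so removing
    its prediction hurts decoding (``"negative"``); a coupled seed that
    carries none of the layer's content removes only contamination
    (``"positive"``); multi-hop cascade carriage is attenuated by
    ``crosstalk_gain²`` per hop and treated as weak. Imagery: all stimulus
    information arrives through the top-down replay of the recalled
    feedforward representation, which carries the apex region's preferred
    layer at full strength and lower layers attenuated by the cascade — the
    effect is ``"negative"`` for layers within two cascade hops of the
    regions that route them into the replay and ``"null"`` for layers the
    replay does not carry at removable strength. Uncoupled regions yield
    ``"null"``.

    Regions are 1-based along the hierarchy; ``feature_layer`` is 1-based.
    """
    K = config.n_regions
    for r in (seed_region, target_region):
        if not 1 <= r <= K:
            raise ValidationError(f"region {r} out of range 1..{K}")
    if not 1 <= feature_layer <= config.n_feature_layers:
        raise ValidationError(f"layer {feature_layer} out of range")
    if seed_region == target_region:
        raise ValidationError("self-distillation has no defined effect sign")
    task = task or config.mode
    if task == "both":
        raise ValidationError("specify task='perception' or 'imagery'")

    crosstalk = config.crosstalk_gain > 0 and config.kappa_bu > 0
    coupled = (config.kappa_td > 0) or crosstalk
    if not coupled:
        return "null"
    if task == "imagery":
        if config.kappa_td == 0:
            return "null"  # nothing is replayed downward
        # the replay is rooted in the apex feedforward pattern: a layer is
        # removable when some region within two cascade hops of the apex
        # routes it there (zero hops when the cascade is off)
        reach = 2 if crosstalk else 0
        carried = any(
            config.preferred_layer(k) == feature_layer
            for k in range(max(1, K - reach), K + 1)
        )
        return "negative" if carried else "null"

    seed_encodes = config.preferred_layer(seed_region) == feature_layer
    seed_inherits = (
        crosstalk
        and seed_region > 1
        and config.preferred_layer(seed_region - 1) == feature_layer
    )
    if seed_encodes or seed_inherits:
        return "negative"
    if config.kappa_td > 0:
        return "positive"
    return "null"
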