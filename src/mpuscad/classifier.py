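"""Three-branch CNN + MLP voxel classifier and its full training protocol.

Each feature group (CUDI 1D, CUDI 4D, SWE) feeds its own small 3D CNN that
maps a cubic patch around the voxel to an embedding; the concatenated
embeddings plus clinical scalars (prostate volume, PSA density) enter an MLP
with a sigmoid output, yielding a per-voxel csPCa probability.  Location
channels (prostate/zone masks, distance to the probe, elevation angle) are
appended to every branch's input so that the quantitative features are not
used to re-learn position.  The default architecture totals ~47k trainable
parameters.

Training protocol: per-feature z-standardization (dataset-wide by default,
with a leakage-safe train-folds-only mode), stratified 7-fold cross-validation
with lesion-size subgroups, branch pretraining on 50%-positive balanced
batches, MLP fine-tuning at the true ~5% prevalence with the CNN weights
frozen, confidence-weighted cross-entropy, Adam without weight regularization,
AWGN + random-offset augmentation, early stopping on validation ROC AUC and
loss stagnation (10-epoch patience, 100 epochs max), and greedy forward
feature selection on validation AUC.  A location-only control classifier
quantifies how much of the performance is positional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .evaluation import weighted_roc_auc
from .reference import ReferenceVolume

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "FoldPlan",
    "ModelBundle",
    "PatientRecord",
    "VoxelTable",
    "DEFAULT_FEATURE_GROUPS",
    "build_model",
    "count_parameters",
    "compute_location_channels",
    "standardize_features",
    "make_folds",
    "weighted_bce",
    "sample_batches",
    "augment",
    "pretrain_branch",
    "finetune_mlp",
    "forward_feature_selection",
    "predict_volume",
    "control_location_model",
    "train_full_model",
]

PARAM_BAND = (46_000, 48_000)

DEFAULT_FEATURE_GROUPS: dict[str, list[str]] = {
    "CUDI_1D": ["kappa", "mu", "appearance_time", "peak_intensity", "wash_in_time"],
    "CUDI_4D": ["cd_v_mag", "cd_D", "sa_corr", "sa_coh", "sa_mi", "ve_H", "ve_H_cond"],
    "SWE": ["swe_sws", "swe_E", "swe_quality"],
}


# --------------------------------------------------------------------------
# specs and containers
# --------------------------------------------------------------------------

@dataclass
class ArchitectureSpec:
    """Branch/MLP layout; the defaults land in the 47k parameter band."""

    branches: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_FEATURE_GROUPS.items()}
    )
    conv_widths: tuple[int, int] = (12, 12)
    embedding: int = 16
    mlp_hidden: tuple[int, int] = (112, 48)
    patch_size: int = 7
    n_location_channels: int = 4
    clinical: tuple[str, ...] = ("volume_cc", "psa_density")

    def branch_in_channels(self, name: str) -> int:
        return len(self.branches[name]) + self.n_location_channels

    @property
    def n_conv(self) -> int:
        # three valid 3x3x3 convolutions consume patch_size - 1 voxels
        return (self.patch_size - 1) // 2


@dataclass
class TrainConfig:
    pretrain_positive_fraction: float = 0.5
    finetune_prevalence: float = 0.05
    lr: float = 1e-3
    batch_size: int = 1024
    max_epochs: int = 100
    patience: int = 10
    awgn_sigma: float = 0.1
    offset_range: float = 0.1
    spatial_offset: bool = False  # alternative reading of "random offset"
    loss_tol: float = 1e-4
    val_subsample: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pretrain_positive_fraction < 1:
            raise ValueError("pretrain_positive_fraction must be in (0, 1)")
        if not 0 < self.finetune_prevalence < 1:
            raise ValueError("finetune_prevalence must be in (0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class FoldPlan:
    fold_of: dict[int, int]  # patient id -> fold
    subgroup_of: dict[int, int]  # patient id -> size subgroup
    k: int = 7

    def split(self, fold: int) -> tuple[list[int], list[int]]:
        train = [p for p, f in self.fold_of.items() if f != fold]
        val = [p for p, f in self.fold_of.items() if f == fold]
        return train, val


@dataclass
class ModelBundle:
    spec: ArchitectureSpec
    branches: dict[str, nn.Sequential]
    heads: dict[str, nn.Dense]  # temporary pretraining heads (not counted)
    mlp: nn.Sequential
    stats: dict | None = None
    seed: int = 0

    def branch_params(self) -> list[nn.Param]:
        return [p for b in self.branches.values() for p in b.params()]

    def embed(self, name: str, patches: np.ndarray) -> np.ndarray:
        out = self.branches[name].forward(patches)
        return out.reshape(out.shape[0], -1)

    def forward(self, patch_dict: dict[str, np.ndarray], clinical: np.ndarray) -> np.ndarray:
        embs = [self.embed(name, patch_dict[name]) for name in self.spec.branches]
        x = np.concatenate(embs + ([clinical] if clinical.size else []), axis=1)
        return self.mlp.forward(x)[:, 0]

    def forward_backward(
        self,
        patch_dict: dict[str, np.ndarray],
        clinical: np.ndarray,
        labels: np.ndarray,
        weights: np.ndarray,
        train_branches: bool,
    ) -> float:
        names = list(self.spec.branches)
        embs = [self.embed(n, patch_dict[n]) for n in names]
        x = np.concatenate(embs + ([clinical] if clinical.size else []), axis=1)
        z = self.mlp.forward(x)[:, 0]
        loss, dz = nn.weighted_bce_logits(z, labels, weights)
        dx = self.mlp.backward(dz[:, None])
        if train_branches:
            ofs = 0
            for n, e in zip(names, embs):
                g = dx[:, ofs:ofs + e.shape[1]]
                self.branches[n].backward(g.reshape(g.shape[0], -1, 1, 1, 1))
                ofs += e.shape[1]
        return loss


# --------------------------------------------------------------------------
# model construction
# --------------------------------------------------------------------------

def _make_branch(spec: ArchitectureSpec, in_c: int, rng: np.random.Generator) -> nn.Sequential:
    # stacked valid 3x3x3 convolutions collapse the patch to 1x1x1; the number
    # of conv layers therefore follows from the patch size (7 -> 3 layers)
    n_conv = spec.n_conv
    if n_conv < 1:
        raise ValueError("patch_size must be >= 3")
    widths = list(spec.conv_widths)
    if len(widths) < n_conv - 1:
        raise ValueError("conv_widths too short for this patch size")
    layers: list[nn.Layer] = []
    c_in = in_c
    for i in range(n_conv - 1):
        layers += [nn.Conv3d(c_in, widths[i], 3, rng), nn.ReLU()]
        c_in = widths[i]
    layers += [nn.Conv3d(c_in, spec.embedding, 3, rng), nn.ReLU(), nn.Flatten()]
    return nn.Sequential(layers)


def build_model(spec: ArchitectureSpec | None = None, seed: int = 0) -> ModelBundle:
    """Deterministically initialized CNN-MLP; warns if the trainable-parameter
    count misses the 46k-48k band the default architecture is tuned to."""
    spec = spec or ArchitectureSpec()
    rng = np.random.default_rng([seed, 77])
    branches = {}
    heads = {}
    for name in spec.branches:
        branches[name] = _make_branch(spec, spec.branch_in_channels(name), rng)
        heads[name] = nn.Dense(spec.embedding, 1, rng)
    h1, h2 = spec.mlp_hidden
    mlp_in = spec.embedding * len(spec.branches) + len(spec.clinical)
    mlp = nn.Sequential([
        nn.Dense(mlp_in, h1, rng), nn.ReLU(),
        nn.Dense(h1, h2, rng), nn.ReLU(),
        nn.Dense(h2, 1, rng),
    ])
    model = ModelBundle(spec=spec, branches=branches, heads=heads, mlp=mlp, seed=seed)
    n = count_parameters(model)
    if spec == ArchitectureSpec() and not PARAM_BAND[0] <= n <= PARAM_BAND[1]:
        warnings.warn(f"default architecture has {n} parameters, outside {PARAM_BAND}")
    return model


def count_parameters(model: ModelBundle) -> int:
    """Trainable parameters of the deployed model (pretraining heads excluded)."""
    return sum(p.size for p in model.branch_params()) + sum(
        p.size for p in model.mlp.params()
    )


# --------------------------------------------------------------------------
# location channels & standardization
# --------------------------------------------------------------------------

def compute_location_channels(
    prostate_mask: np.ndarray,
    pz_mask: np.ndarray,
    voxel_size_mm: float,
    probe_standoff_mm: float = 10.0,
) -> np.ndarray:
    """(4, X, Y, Z): prostate mask, PZ mask, distance to probe, elevation angle.

    Distance is Euclidean mm from the probe origin; elevation is the fan angle
    of the voxel about the probe axis.  The two continuous channels use fixed
    physical scalings (100 mm, pi rad) so they are comparable across patients
    without dataset statistics.
    """
    from .phantom import world_coordinates

    X, Y, Z = world_coordinates(prostate_mask.shape, voxel_size_mm, probe_standoff_mm)
    dist = np.sqrt(X**2 + Y**2 + Z**2)
    elev = np.arctan2(Y, X)
    return np.stack([
        prostate_mask.astype(float),
        pz_mask.astype(float),
        dist / 100.0,
        elev / np.pi,
    ])


@dataclass
class PatientRecord:
    """Feature maps, location channels, clinical scalars and reference for one
    patient, all on the common prostate grid."""

    pid: int
    features: dict[str, np.ndarray]  # name -> (X, Y, Z), NaN = missing
    location: np.ndarray  # (4, X, Y, Z)
    clinical: dict[str, float]
    reference: ReferenceVolume
    lesion_size_mm3: float = 0.0


def standardize_features(
    patients: list[PatientRecord],
    stats_scope: str = "entire_dataset",
    train_pids: list[int] | None = None,
) -> dict[str, dict[str, float]]:
    """Per-feature z-scoring over masked voxels; missing values become 0.

    ``stats_scope`` is ``'entire_dataset'`` (statistics over every patient) or
    ``'train_folds_only'`` (leakage-safe: statistics from ``train_pids`` but
    applied everywhere).  Zero-variance features are left centered and
    flagged.  Returns the persisted stats record and replaces each feature
    volume with its standardized version in place.
    """
    if stats_scope not in ("entire_dataset", "train_folds_only"):
        raise ValueError("stats_scope must be 'entire_dataset' or 'train_folds_only'")
    if stats_scope == "train_folds_only":
        if train_pids is None:
            raise ValueError("train_folds_only scope needs train_pids")
        pool = [p for p in patients if p.pid in set(train_pids)]
    else:
        pool = patients
    names = sorted({n for p in patients for n in p.features})
    stats: dict[str, dict[str, float]] = {"__scope__": {"scope": stats_scope}}  # type: ignore[dict-item]
    for name in names:
        vals = np.concatenate([
            p.features[name][p.reference.prostate_mask].ravel()
            for p in pool if name in p.features
        ])
        vals = vals[np.isfinite(vals)]
        mean = float(vals.mean()) if vals.size else 0.0
        sd = float(vals.std()) if vals.size else 0.0
        constant = sd < 1e-12
        stats[name] = {"mean": mean, "sd": sd if not constant else 1.0,
                       "constant": float(constant)}
        for p in patients:
            if name in p.features:
                z = (p.features[name] - mean) / stats[name]["sd"]
                p.features[name] = np.nan_to_num(z, nan=0.0, posinf=0.0, neginf=0.0)
    # clinical scalars are standardized over the same scope
    clin_names = sorted({c for p in patients for c in p.clinical})
    for cname in clin_names:
        vals = np.array([p.clinical[cname] for p in pool if cname in p.clinical])
        mean = float(vals.mean()) if vals.size else 0.0
        sd = float(vals.std()) if vals.size else 0.0
        sd = sd if sd > 1e-12 else 1.0
        stats[f"clinical:{cname}"] = {"mean": mean, "sd": sd, "constant": 0.0}
        for p in patients:
            if cname in p.clinical:
                p.clinical[cname] = (p.clinical[cname] - mean) / sd
    return stats


# --------------------------------------------------------------------------
# folds
# --------------------------------------------------------------------------

def make_folds(
    patient_ids: list[int],
    lesion_sizes: dict[int, float],
    k: int = 7,
    seed: int = 0,
) -> FoldPlan:
    """Stratified folds with lesion-size subgroups kept proportional.

    Subgroups: no-csPCa (size 0) plus terciles of lesion size among csPCa
    patients; round-robin assignment within each subgroup after a seeded
    shuffle keeps per-fold subgroup counts within one patient of each other.
    """
    rng = np.random.default_rng([seed, 55])
    sizes = np.array([lesion_sizes.get(p, 0.0) for p in patient_ids])
    pos = sizes > 0
    subgroup = np.zeros(len(patient_ids), dtype=int)
    if pos.any():
        cuts = np.quantile(sizes[pos], [1 / 3, 2 / 3])
        subgroup[pos] = 1 + np.searchsorted(cuts, sizes[pos], side="right")
    fold_of: dict[int, int] = {}
    subgroup_of: dict[int, int] = {}
    start = 0
    for g in np.unique(subgroup):
        members = [patient_ids[i] for i in np.flatnonzero(subgroup == g)]
        if len(members) < k:
            warnings.warn(
                f"subgroup {g} has {len(members)} patients < k={k}: best-effort balance"
            )
        order = rng.permutation(len(members))
        for pos_i, idx in enumerate(order):
            fold_of[members[idx]] = (start + pos_i) % k
            subgroup_of[members[idx]] = int(g)
        start += len(members)  # stagger so small subgroups don't pile on fold 0
    return FoldPlan(fold_of=fold_of, subgroup_of=subgroup_of, k=k)


# --------------------------------------------------------------------------
# loss, sampling, augmentation
# --------------------------------------------------------------------------

def weighted_bce(pred: np.ndarray, label: np.ndarray, weight: np.ndarray) -> float:
    """Confidence-weighted binary cross-entropy on probabilities.

    Predictions are clipped to [1e-7, 1 - 1e-7] before the log.
    """
    p = np.clip(np.asarray(pred, dtype=float).ravel(), 1e-7, 1.0 - 1e-7)
    y = np.asarray(label, dtype=float).ravel()
    w = np.asarray(weight, dtype=float).ravel()
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float(-np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p))) / np.sum(w))


def sample_batches(
    labels: np.ndarray,
    positive_fraction: float,
    batch_size: int,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Index batches with a fixed positive fraction by undersampling.

    One epoch is a single pass over the minority class; the majority class is
    re-drawn (shuffled, cycled) to fill each batch to its exact class counts.
    """
    y = np.asarray(labels).astype(bool).ravel()
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng([seed, 33])
    n_pos_b = max(int(round(batch_size * positive_fraction)), 1)
    n_neg_b = batch_size - n_pos_b
    minority_is_pos = pos.size * (1 - positive_fraction) <= neg.size * positive_fraction
    pos = rng.permutation(pos)
    neg = rng.permutation(neg)

    def cycled(arr: np.ndarray, n: int) -> np.ndarray:
        reps = int(np.ceil(n / arr.size))
        return np.concatenate([rng.permutation(arr) for _ in range(reps)])[:n]

    batches = []
    if minority_is_pos:
        n_batches = int(np.ceil(pos.size / n_pos_b))
        neg_stream = cycled(neg, n_batches * n_neg_b)
        for i in range(n_batches):
            p = pos[i * n_pos_b:(i + 1) * n_pos_b]
            if p.size < n_pos_b:
                p = np.concatenate([p, rng.choice(pos, n_pos_b - p.size, replace=True)])
            n = neg_stream[i * n_neg_b:(i + 1) * n_neg_b]
            batches.append(rng.permutation(np.concatenate([p, n])))
    else:
        n_batches = int(np.ceil(neg.size / n_neg_b))
        pos_stream = cycled(pos, n_batches * n_pos_b)
        for i in range(n_batches):
            n = neg[i * n_neg_b:(i + 1) * n_neg_b]
            if n.size < n_neg_b:
                n = np.concatenate([n, rng.choice(neg, n_neg_b - n.size, replace=True)])
            p = pos_stream[i * n_pos_b:(i + 1) * n_pos_b]
            batches.append(rng.permutation(np.concatenate([p, n])))
    return batches


def augment(
    patch_dict: dict[str, np.ndarray],
    awgn_sigma: float,
    offset_range: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """AWGN per element plus a per-sample, per-feature constant offset.

    Operates on standardized inputs; labels and weights are untouched (they
    live outside the patch dict).
    """
    if awgn_sigma < 0:
        raise ValueError("awgn_sigma must be non-negative")
    if awgn_sigma == 0 and offset_range == 0:
        return patch_dict
    out = {}
    for name, x in patch_dict.items():
        x = x.copy()
        if awgn_sigma > 0:
            if x.dtype == np.float32:
                x += awgn_sigma * rng.standard_normal(x.shape, dtype=np.float32)
            else:
                x += awgn_sigma * rng.standard_normal(x.shape)
        if offset_range > 0:
            off = rng.uniform(-offset_range, offset_range, size=x.shape[:2])
            x += off[:, :, None, None, None].astype(x.dtype)
        out[name] = x
    return out


# --------------------------------------------------------------------------
# voxel table / patch extraction
# --------------------------------------------------------------------------

class VoxelTable:
    """Flat voxel table over a set of patients with patch extraction.

    Rows are (patient index, voxel coordinates, label, weight).  Feature and
    location volumes are padded once so any patch is a fancy-index gather.
    """

    def __init__(
        self,
        patients: list[PatientRecord],
        spec: ArchitectureSpec,
        max_voxels_per_patient: int | None = None,
        seed: int = 0,
    ):
        self.patients = patients
        self.spec = spec
        h = spec.patch_size // 2
        self._pad = h
        rng = np.random.default_rng([seed, 21])
        self._vols: list[dict[str, np.ndarray]] = []
        self._cache: dict[str, np.ndarray] = {}
        rows_pid, rows_xyz, rows_y, rows_w = [], [], [], []
        rows_pz, rows_tz = [], []
        for i, p in enumerate(patients):
            vols = {}
            for name, feats in spec.branches.items():
                chans = [p.features[f] for f in feats] + list(p.location)
                arr = np.stack(chans).astype(np.float32)
                vols[name] = np.pad(arr, ((0, 0),) + ((h, h),) * 3)
            self._vols.append(vols)
            m = p.reference.prostate_mask
            xyz = np.argwhere(m)
            if max_voxels_per_patient is not None and len(xyz) > max_voxels_per_patient:
                lab = p.reference.label[m].astype(bool)
                pos_idx = np.flatnonzero(lab)
                neg_idx = np.flatnonzero(~lab)
                n_pos = min(pos_idx.size, max(max_voxels_per_patient // 4, 1))
                n_neg = max_voxels_per_patient - n_pos
                keep = np.concatenate([
                    rng.choice(pos_idx, n_pos, replace=False) if pos_idx.size else np.array([], int),
                    rng.choice(neg_idx, min(n_neg, neg_idx.size), replace=False),
                ])
                xyz = xyz[keep]
            rows_pid.append(np.full(len(xyz), i))
            rows_xyz.append(xyz)
            rows_y.append(p.reference.label[tuple(xyz.T)])
            rows_w.append(p.reference.weight[tuple(xyz.T)])
            rows_pz.append(p.reference.pz_mask[tuple(xyz.T)])
            rows_tz.append(p.reference.tz_mask[tuple(xyz.T)])
        self.pid = np.concatenate(rows_pid)
        self.xyz = np.concatenate(rows_xyz)
        self.label = np.concatenate(rows_y).astype(np.int8)
        self.weight = np.concatenate(rows_w).astype(float)
        self.pz = np.concatenate(rows_pz).astype(bool)
        self.tz = np.concatenate(rows_tz).astype(bool)
        self._clin = np.array([
            [p.clinical.get(c, 0.0) for c in spec.clinical] for p in patients
        ])

    def __len__(self) -> int:
        return len(self.label)

    def _group_cache(self, name: str) -> np.ndarray:
        # gather every row's patch once; epochs then just index this tensor
        if name not in self._cache:
            s = self.spec.patch_size
            n_c = self._vols[0][name].shape[0]
            patches = np.empty((len(self.label), n_c, s, s, s), dtype=np.float32)
            for j in range(len(self.label)):
                x, y, z = self.xyz[j]
                patches[j] = self._vols[self.pid[j]][name][:, x:x + s, y:y + s, z:z + s]
            self._cache[name] = patches
        return self._cache[name]

    def patches(self, rows: np.ndarray, groups: list[str] | None = None) -> dict[str, np.ndarray]:
        groups = groups if groups is not None else list(self.spec.branches)
        return {name: self._group_cache(name)[rows] for name in groups}

    def clinical(self, rows: np.ndarray) -> np.ndarray:
        return self._clin[self.pid[rows]].astype(np.float32)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _val_scores_branch(model, name, table, rows, batch=4096):
    zs = []
    for i in range(0, len(rows), batch):
        r = rows[i:i + batch]
        emb = model.embed(name, table.patches(r, [name])[name])
        zs.append(model.heads[name].forward(emb)[:, 0])
    return np.concatenate(zs)


def _val_scores_full(model, table, rows, batch=4096):
    zs = []
    for i in range(0, len(rows), batch):
        r = rows[i:i + batch]
        zs.append(model.forward(table.patches(r), table.clinical(r)))
    return np.concatenate(zs)


def _early_stop(history_auc, history_loss, patience, loss_tol) -> bool:
    if len(history_auc) > patience:
        best = max(history_auc)
        if max(history_auc[-patience:]) < best:
            return True
    if len(history_loss) >= patience:
        recent = history_loss[-patience:]
        if max(recent) - min(recent) < loss_tol:
            return True
    return False


def _snapshot(params: list[nn.Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def _restore(params: list[nn.Param], snap: list[np.ndarray]) -> None:
    for p, s in zip(params, snap):
        p.value[...] = s


def _subsample_rows(n: int, cap: int, rng: np.random.Generator) -> np.ndarray:
    rows = np.arange(n)
    if n > cap:
        rows = np.sort(rng.choice(n, cap, replace=False))
    return rows


def pretrain_branch(
    model: ModelBundle,
    name: str,
    train_table: VoxelTable,
    val_table: VoxelTable,
    config: TrainConfig,
) -> dict:
    """Train one CNN branch (with its temporary head) on balanced batches.

    50% positive sampling, weighted BCE, AWGN+offset augmentation, early stop
    when validation ROC AUC stops improving or losses stagnate (both over
    ``patience`` epochs); restores the best-AUC weights.  Divergence (non-
    finite loss) aborts with the training state attached to the exception.
    """
    rng = np.random.default_rng([config.seed, hash(name) % (2**31)])
    params = model.branches[name].params() + model.heads[name].params()
    opt = nn.Adam(params, lr=config.lr)
    val_rows = _subsample_rows(len(val_table), config.val_subsample, rng)
    best_auc, best_snap = -np.inf, _snapshot(params)
    auc_hist: list[float] = []
    loss_hist: list[float] = []
    log = []
    for epoch in range(config.max_epochs):
        batches = sample_batches(
            train_table.label, config.pretrain_positive_fraction,
            config.batch_size, rng,
        )
        ep_loss = 0.0
        for rows in batches:
            x = train_table.patches(rows, [name])
            x = augment(x, config.awgn_sigma, config.offset_range, rng)
            emb = model.embed(name, x[name])
            z = model.heads[name].forward(emb)[:, 0]
            loss, dz = nn.weighted_bce_logits(
                z, train_table.label[rows], train_table.weight[rows]
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"branch {name} diverged at epoch {epoch}; state={log[-3:]}"
                )
            opt.zero_grad()
            demb = model.heads[name].backward(dz[:, None])
            model.branches[name].backward(demb.reshape(demb.shape[0], -1, 1, 1, 1))
            opt.step()
            ep_loss += loss
        ep_loss /= max(len(batches), 1)
        zv = _val_scores_branch(model, name, val_table, val_rows)
        try:
            auc = weighted_roc_auc(
                zv, val_table.label[val_rows], val_table.weight[val_rows]
            ).auc
        except ValueError:
            auc = 0.5
        auc_hist.append(auc)
        loss_hist.append(ep_loss)
        log.append({"epoch": epoch, "loss": ep_loss, "val_auc": auc})
        if auc > best_auc:
            best_auc, best_snap = auc, _snapshot(params)
        if _early_stop(auc_hist, loss_hist, config.patience, config.loss_tol):
            break
    _restore(params, best_snap)
    return {"val_auc": best_auc, "epochs": len(log), "log": log}


def finetune_mlp(
    model: ModelBundle,
    train_table: VoxelTable,
    val_table: VoxelTable,
    config: TrainConfig,
) -> dict:
    """Fine-tune only the MLP head at the true (~5%) prevalence.

    The CNN branches are frozen; a bitwise check asserts their weights are
    unchanged afterwards.
    """
    rng = np.random.default_rng([config.seed, 99])
    frozen_before = _snapshot(model.branch_params())
    params = model.mlp.params()
    opt = nn.Adam(params, lr=config.lr)
    val_rows = _subsample_rows(len(val_table), config.val_subsample, rng)
    best_auc, best_snap = -np.inf, _snapshot(params)
    auc_hist: list[float] = []
    loss_hist: list[float] = []
    log = []
    for epoch in range(config.max_epochs):
        batches = sample_batches(
            train_table.label, config.finetune_prevalence, config.batch_size, rng
        )
        ep_loss = 0.0
        for rows in batches:
            x = train_table.patches(rows)
            x = augment(x, config.awgn_sigma, config.offset_range, rng)
            opt.zero_grad()
            loss = model.forward_backward(
                x, train_table.clinical(rows),
                train_table.label[rows], train_table.weight[rows],
                train_branches=False,
            )
            if not np.isfinite(loss):
                raise FloatingPointError(f"MLP fine-tune diverged at epoch {epoch}")
            opt.step()
            ep_loss += loss
        ep_loss /= max(len(batches), 1)
        zv = _val_scores_full(model, val_table, val_rows)
        try:
            auc = weighted_roc_auc(
                zv, val_table.label[val_rows], val_table.weight[val_rows]
            ).auc
        except ValueError:
            auc = 0.5
        auc_hist.append(auc)
        loss_hist.append(ep_loss)
        log.append({"epoch": epoch, "loss": ep_loss, "val_auc": auc})
        if auc > best_auc:
            best_auc, best_snap = auc, _snapshot(params)
        if _early_stop(auc_hist, loss_hist, config.patience, config.loss_tol):
            break
    _restore(params, best_snap)
    frozen_after = _snapshot(model.branch_params())
    for a, b in zip(frozen_before, frozen_after):
        if not np.array_equal(a, b):
            raise AssertionError("branch weights changed during MLP fine-tuning")
    return {"val_auc": best_auc, "epochs": len(log), "log": log}


def train_full_model(
    spec: ArchitectureSpec,
    train_table: VoxelTable,
    val_table: VoxelTable,
    config: TrainConfig,
) -> tuple[ModelBundle, dict]:
    """Pretrain each branch independently, then fine-tune the MLP."""
    model = build_model(spec, seed=config.seed)
    info = {}
    for name in spec.branches:
        info[name] = pretrain_branch(model, name, train_table, val_table, config)
    info["mlp"] = finetune_mlp(model, train_table, val_table, config)
    return model, info


# --------------------------------------------------------------------------
# feature selection, prediction, control model
# --------------------------------------------------------------------------

def forward_feature_selection(
    candidates: list[str],
    score_fn,
    epsilon: float = 0.001,
) -> tuple[list[str], list[dict]]:
    """Greedy forward selection maximizing mean validation ROC AUC.

    ``score_fn(feature_list) -> float`` trains/evaluates a model on the given
    feature set; candidates are added while the best improvement exceeds
    ``epsilon``.  Returns the selected set and the full trace.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate features")
    selected: list[str] = []
    remaining = list(candidates)
    best_auc = -np.inf
    trace: list[dict] = []
    while remaining:
        scores = {c: score_fn(selected + [c]) for c in remaining}
        c_best = max(scores, key=scores.get)
        gain = scores[c_best] - (best_auc if np.isfinite(best_auc) else 0.0)
        trace.append({"candidate": c_best, "auc": scores[c_best],
                      "all_scores": scores, "accepted": gain > epsilon})
        if gain <= epsilon:
            break
        selected.append(c_best)
        remaining.remove(c_best)
        best_auc = scores[c_best]
    return selected, trace


def predict_volume(
    model: ModelBundle,
    patient: PatientRecord,
    batch: int = 4096,
) -> np.ndarray:
    """Dense per-voxel probability map; NaN outside the prostate mask.

    The patient's features must already be standardized with the persisted
    stats record attached to the model.
    """
    if model.stats is None:
        raise ValueError("model carries no standardization stats; train first")
    table = VoxelTable([patient], model.spec)
    z = _val_scores_full(model, table, np.arange(len(table)), batch=batch)
    out = np.full(patient.reference.prostate_mask.shape, np.nan)
    out[tuple(table.xyz.T)] = nn.sigmoid(z)
    return out


def control_location_model(spec: ArchitectureSpec | None = None) -> ArchitectureSpec:
    """Architecture for the location-only control classifier.

    Same scaffold, but the single branch sees only the location channels and
    no clinical scalars; its AUC quantifies how much performance is positional.
    """
    base = spec or ArchitectureSpec()
    return ArchitectureSpec(
        branches={"LOCATION": []},
        conv_widths=base.conv_widths,
        embedding=base.embedding,
        mlp_hidden=base.mlp_hidden,
        patch_size=base.patch_size,
        n_location_channels=base.n_location_channels,
        clinical=(),
    )
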