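"""Losses, label transforms, dataset splits, metrics and training loops."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score

from .nn import Adam, Tensor, functional as F
from .protein_vae import kl_divergence

__all__ = [
    "PairRecord", "SplitSpec", "TrainConfig",
    "kd_to_pkd", "encode_region_labels", "rwing_loss", "combined_loss",
    "mse_loss", "split_dataset", "drop_conflicting_duplicates",
    "concordance_index", "rm2_score", "aupr_score", "region_accuracy",
    "evaluate_affinity", "train", "cross_validate",
]


# -------------------------------------------------------------------- types
@dataclass
class PairRecord:
    ligand_smiles: str
    protein_seq: str
    affinity: float
    region: tuple[int, int] | None = None   # [start, end), 0-based

    def __post_init__(self):
        if not np.isfinite(self.affinity):
            raise ValueError("affinity must be finite")
        if self.region is not None:
            start, end = self.region
            if not 0 <= start < end <= len(self.protein_seq):
                raise ValueError(
                    f"region {self.region} outside [0, {len(self.protein_seq)})")


@dataclass
class SplitSpec:
    mode: str = "random"                       # random | cold_ligand | cold_target
    fractions: tuple = (4 / 6, 1 / 6, 1 / 6)   # train/val/test (random mode)
    val_entity_frac: float = 0.05              # cold modes
    test_entity_frac: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("random", "cold_ligand", "cold_target"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 32
    lr: float = 1e-3
    psi: float = 0.4              # affinity weight in the joint loss
    beta_kl: float = 1e-3
    lambda_recon: float = 0.1
    rwing_thresh: float = 0.1
    rwing_w: float = 2.0
    rwing_eps: float = 0.5
    patience: int = 10
    region_scale: int = 10


# ----------------------------------------------------------- label transforms
def kd_to_pkd(kd: float) -> float:
    """pKd = -log10(Kd / 1e9) for Kd given in nM."""
    if kd <= 0:
        raise ValueError(f"Kd must be positive, got {kd}")
    return float(-np.log10(kd / 1e9))


def encode_region_labels(rec: PairRecord, max_positions: int) -> np.ndarray:
    """theta_p-length vector: affinity inside the labelled region, 0 outside."""
    if rec.region is None:
        raise ValueError("record has no region label; use the affinity-only "
                         "regime for unlabelled pairs")
    start, end = rec.region
    start, end = max(0, start), min(end, max_positions)
    if start >= end:
        raise ValueError(f"region {rec.region} is empty after truncation "
                         f"to {max_positions} positions")
    values = np.zeros(max_positions)
    values[start:end] = rec.affinity
    return values


# -------------------------------------------------------------------- losses
def rwing_loss(residuals, r_thresh: float = 0.1, w: float = 2.0,
               eps: float = 0.5):
    """Rectified wing penalty, averaged over elements.

    0 inside the dead zone |x| < r_thresh; w*ln(1 + (|x|-r_thresh)/eps)
    for r_thresh <= |x| < w; |x| - C beyond, with C chosen for continuity.
    Accepts numpy arrays or Tensors.
    """
    if not (w > r_thresh >= 0):
        raise ValueError(f"need w > r_thresh >= 0, got w={w}, r_thresh={r_thresh}")
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    x = F.absolute(residuals)
    data = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=float)
    m_log = ((data >= r_thresh) & (data < w)).astype(float)
    m_lin = (data >= w).astype(float)
    c = w - w * np.log1p((w - r_thresh) / eps)
    # |x - r_thresh| keeps the log argument positive inside the dead zone,
    # where the branch is masked out anyway
    log_branch = F.log(F.absolute(x - r_thresh) * (1.0 / eps) + 1.0) * w
    per_element = log_branch * m_log + (x - c) * m_lin
    return per_element.mean()


def combined_loss(l_ba, l_br, psi: float = 0.4):
    """Loss = psi * L_BA + (1 - psi) * L_BR."""
    if not 0.0 <= psi <= 1.0:
        raise ValueError(f"psi must be in [0, 1], got {psi}")
    return l_ba * psi + l_br * (1.0 - psi)


def mse_loss(pred, truth):
    diff = pred - truth
    return (diff * diff).mean()


# -------------------------------------------------------------------- splits
def drop_conflicting_duplicates(records):
    """Deduplicate identical pairs; drop pairs whose (ligand, protein) key
    carries more than one distinct affinity label."""
    by_key: dict = {}
    for rec in records:
        by_key.setdefault((rec.ligand_smiles, rec.protein_seq), []).append(rec)
    kept = []
    for group in by_key.values():
        labels = {round(r.affinity, 12) for r in group}
        if len(labels) == 1:
            kept.append(group[0])
    return kept


def split_dataset(records, spec: SplitSpec):
    """Random 4:1:1 pair split, or cold-entity split with 5% of entities in
    validation and 10% in test (their pairs removed from training)."""
    if not records:
        raise ValueError("no records to split")
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "random":
        idx = rng.permutation(len(records))
        n = len(records)
        n_val = int(round(n * spec.fractions[1]))
        n_test = int(round(n * spec.fractions[2]))
        test = [records[i] for i in idx[:n_test]]
        val = [records[i] for i in idx[n_test:n_test + n_val]]
        train_set = [records[i] for i in idx[n_test + n_val:]]
        return train_set, val, test

    key = (lambda r: r.ligand_smiles) if spec.mode == "cold_ligand" \
        else (lambda r: r.protein_seq)
    entities = sorted({key(r) for r in records})
    n_ent = len(entities)
    n_val_e = int(round(n_ent * spec.val_entity_frac))
    n_test_e = int(round(n_ent * spec.test_entity_frac))
    if n_val_e < 1 or n_test_e < 1 or n_val_e + n_test_e >= n_ent:
        raise ValueError(
            f"too few distinct entities ({n_ent}) for a cold split")
    order = rng.permutation(n_ent)
    val_set = {entities[i] for i in order[:n_val_e]}
    test_set = {entities[i] for i in order[n_val_e:n_val_e + n_test_e]}
    train_set = [r for r in records if key(r) not in val_set
                 and key(r) not in test_set]
    val = [r for r in records if key(r) in val_set]
    test = [r for r in records if key(r) in test_set]
    return train_set, val, test


# ------------------------------------------------------------------- metrics
def concordance_index(pred, truth) -> float:
    """Fraction of correctly ranked pairs (ties in pred count 0.5)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1 or pred.size < 2:
        raise ValueError("pred and truth must be equal-length vectors (n >= 2)")
    d_truth = truth[:, None] - truth[None, :]
    ordered = d_truth > 0
    n_pairs = int(ordered.sum())
    if n_pairs == 0:
        raise ValueError("truth has no strictly ordered pair; CI undefined")
    d_pred = pred[:, None] - pred[None, :]
    score = np.where(d_pred > 0, 1.0, np.where(d_pred == 0, 0.5, 0.0))
    return float(score[ordered].sum() / n_pairs)


def rm2_score(pred, truth) -> float:
    """rm^2 = r^2 * (1 - sqrt(|r^2 - r0^2|)) with r0^2 the squared
    correlation through the origin (truth regressed on pred)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.size < 3 or pred.shape != truth.shape:
        raise ValueError("need equal-length vectors with n >= 3")
    if pred.std() == 0 or truth.std() == 0:
        raise ValueError("zero variance input")
    r = np.corrcoef(pred, truth)[0, 1]
    r2 = r * r
    k = float(np.sum(truth * pred) / np.sum(pred * pred))
    ss_res = np.sum((truth - k * pred) ** 2)
    ss_tot = np.sum((truth - truth.mean()) ** 2)
    r02 = 1.0 - ss_res / ss_tot
    return float(r2 * (1.0 - np.sqrt(abs(r2 - r02))))


def aupr_score(pred, truth, binarize_threshold: float) -> float:
    """Area under the precision-recall curve of pred against
    (truth >= threshold), step integration."""
    truth = np.asarray(truth, dtype=float)
    labels = (truth >= binarize_threshold).astype(int)
    if labels.min() == labels.max():
        raise ValueError(
            f"binarizing at {binarize_threshold} leaves a single class")
    return float(average_precision_score(labels, np.asarray(pred, dtype=float)))


def region_accuracy(predicted_regions, true_sites, R: int) -> float:
    """Fraction of pairs whose true site intersects the predicted width-R
    half-open window."""
    if len(predicted_regions) != len(true_sites):
        raise ValueError("predicted_regions and true_sites length mismatch")
    if not predicted_regions:
        raise ValueError("empty input")
    hits = 0
    for (start, end), site in zip(predicted_regions, true_sites):
        if end - start != R:
            raise ValueError(f"region ({start},{end}) does not have width {R}")
        ts, te = (site, site + 1) if np.isscalar(site) else site
        if max(start, ts) < min(end, te):
            hits += 1
    return hits / len(predicted_regions)


def evaluate_affinity(pred, truth, aupr_threshold: float = 7.0) -> dict:
    """CI, MSE, rm2 and (when both classes exist) AUPR."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    out = {
        "ci": concordance_index(pred, truth),
        "mse": float(np.mean((pred - truth) ** 2)),
        "rm2": rm2_score(pred, truth),
    }
    labels = truth >= aupr_threshold
    if labels.min() != labels.max():
        out["aupr"] = aupr_score(pred, truth, aupr_threshold)
    return out


# ------------------------------------------------------------------ training
def _region_label_matrix(records, max_positions: int):
    labels = np.zeros((len(records), max_positions))
    has = np.zeros(len(records), dtype=bool)
    for i, rec in enumerate(records):
        if rec.region is not None:
            labels[i] = encode_region_labels(rec, max_positions)
            has[i] = True
    return labels, has


def train(model, records, regime: str = "affinity_only",
          config: TrainConfig | None = None, seed: int = 0,
          val_records=None, verbose: bool = False):
    """Train a :class:`~mgbind.model.BindingModel`.

    regime="affinity_only" minimises MSE (+ KL and reconstruction terms);
    regime="joint" minimises psi*MSE + (1-psi)*Rwing on region labels.
    Returns (model, history); the model carries the best-validation
    weights when ``val_records`` is given.
    """
    from .model import collate

    if regime not in ("affinity_only", "joint"):
        raise ValueError(f"unknown regime {regime!r}")
    config = config or TrainConfig()
    cfg = model.cfg
    batch_all = collate(records, cfg, model.vocab)
    y_all = np.array([r.affinity for r in records])
    region_labels, has_region = _region_label_matrix(records, cfg.max_kmers)
    if regime == "joint" and not has_region.any():
        raise ValueError("joint regime requires region labels on the "
                         "training records")

    val_batch = None
    if val_records:
        val_batch = collate(val_records, cfg, model.vocab)
        y_val = np.array([r.affinity for r in val_records])

    rng = np.random.default_rng(seed)
    optimizer = Adam(model.parameters(), lr=config.lr)
    model.train()
    history = []
    best = {"mse": np.inf, "state": None, "epoch": -1}
    n = len(records)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, config.batch_size):
            sel = order[lo:lo + config.batch_size]
            batch = {k: v[sel] for k, v in batch_all.items()}
            out = model.forward(batch, rng=rng)
            l_ba = mse_loss(out["affinity"], y_all[sel])
            kl = kl_divergence(out["mu"], out["log_var"]).mean()
            rec_diff = (out["reconstruction"] - batch["recon_target"]) \
                * batch["kmer_mask"]
            l_rec = (rec_diff * rec_diff).mean()
            if regime == "joint":
                lab_idx = np.where(has_region[sel])[0]
                if lab_idx.size:
                    resid = (out["response"]
                             - region_labels[sel])[lab_idx]
                    l_br = rwing_loss(resid, config.rwing_thresh,
                                      config.rwing_w, config.rwing_eps)
                    loss = combined_loss(l_ba, l_br, config.psi)
                else:
                    loss = l_ba
            else:
                loss = l_ba
            loss = loss + kl * config.beta_kl + l_rec * config.lambda_recon
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.item()))
        entry = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if val_batch is not None:
            model.eval()
            pred_val = model.forward(val_batch)["affinity"].data
            model.train()
            entry["val_mse"] = float(np.mean((pred_val - y_val) ** 2))
            if len(set(y_val)) > 1:
                entry["val_ci"] = concordance_index(pred_val, y_val)
            if entry["val_mse"] < best["mse"] - 1e-12:
                best = {"mse": entry["val_mse"],
                        "state": copy.deepcopy(model.state_dict()),
                        "epoch": epoch}
        history.append(entry)
        if verbose:
            print(f"epoch {epoch}: {entry}")
        if (val_batch is not None and best["epoch"] >= 0
                and epoch - best["epoch"] >= config.patience):
            break
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    model.eval()
    return model, history


def cross_validate(model_factory, records, n_folds: int = 5,
                   n_repeats: int = 1, config: TrainConfig | None = None,
                   regime: str = "affinity_only", seed: int = 0):
    """Repeated k-fold cross-validation; returns per-fold metric dicts."""
    records = list(records)
    results = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(seed + rep)
        idx = rng.permutation(len(records))
        folds = np.array_split(idx, n_folds)
        for f, test_idx in enumerate(folds):
            test = [records[i] for i in test_idx]
            train_recs = [records[i] for i in idx if i not in set(test_idx)]
            model = model_factory()
            model, _ = train(model, train_recs, regime=regime, config=config,
                             seed=seed + rep)
            batch = None
            from .model import collate
            batch = collate(test, model.cfg, model.vocab)
            pred = model.forward(batch)["affinity"].data
            truth = np.array([r.affinity for r in test])
            results.append({"repeat": rep, "fold": f,
                            **evaluate_affinity(pred, truth)})
    return results
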