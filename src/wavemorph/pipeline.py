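"""Training, inference and evaluation orchestration.

The training loop follows the standard unsupervised registration recipe:
Adam, batch size 1, learning rate 1e-4 by default, optional tri-axis flip
augmentation applied identically to both images of a pair, similarity +
lambda-weighted diffusion loss, and checkpoint selection by best validation
Dice.  One epoch is one pass over the configured pair list.

Volumes whose extents do not meet the network's divisibility requirement
are edge-padded and the predicted field is cropped back, so the loss and
all metrics are always computed on the original grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .autodiff import Tensor
from .metrics import dice_per_structure, folding_ratio, summarize_dice
from .network import ModelConfig, WaveMorph
from .nn import Adam
from .objectives import LossConfig, total_loss
from .io import read_nifti, write_nifti
from .synthetic import SynthPair
from .warp import warp


@dataclass
class RunConfig:
    """Everything a training run needs.

    ``flip_augment`` is the per-axis flip probability (0.5 for atlas-style
    runs, 0 for inter-patient-style runs, where augmentation is disabled to
    preserve anatomical topology).
    """

    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    lr: float = 1e-4
    batch_size: int = 1
    epochs: int = 100
    flip_augment: float = 0.5
    seed: int = 0
    val_interval: int = 10

    @classmethod
    def atlas_defaults(cls, **kw) -> "RunConfig":
        """NCC (9^3 windows), lambda=1, tri-axis flipping p=0.5."""
        kw.setdefault("loss", LossConfig(similarity="ncc", lam=1.0))
        kw.setdefault("flip_augment", 0.5)
        return cls(**kw)

    @classmethod
    def interpatient_defaults(cls, **kw) -> "RunConfig":
        """MSE, lambda=0.02, no spatial augmentation."""
        kw.setdefault("loss", LossConfig(similarity="mse", lam=0.02))
        kw.setdefault("flip_augment", 0.0)
        return cls(**kw)

    def to_dict(self) -> dict:
        return {"model": self.model.to_dict(), "loss": self.loss.to_dict(),
                "lr": self.lr, "batch_size": self.batch_size,
                "epochs": self.epochs, "flip_augment": self.flip_augment,
                "seed": self.seed, "val_interval": self.val_interval}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "model" in d:
            d["model"] = ModelConfig.from_dict(d["model"])
        if "loss" in d:
            d["loss"] = LossConfig.from_dict(d["loss"])
        return cls(**d)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# -- padding to the network's divisibility requirement ---------------------

def pad_to_multiple(vol: np.ndarray, multiple: int = 16):
    """Edge-pad trailing ends of each spatial axis; returns (padded, crop)
    where `crop` is the slice tuple recovering the original grid."""
    shape = vol.shape[-3:]
    pads = [(multiple - s % multiple) % multiple for s in shape]
    crop = tuple(slice(0, s) for s in shape)
    if not any(pads):
        return vol, crop
    width = [(0, 0)] * (vol.ndim - 3) + [(0, p) for p in pads]
    return np.pad(vol, width, mode="edge"), crop


# -- augmentation ----------------------------------------------------------

def augment_flip(m: np.ndarray, f: np.ndarray, prob: float, seed, *extras):
    """Random tri-axis flipping: each spatial axis is flipped with
    probability `prob`, identically for both volumes and any extras
    (label maps).  Deterministic under `seed` (an int or Generator)."""
    if m.shape != f.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {f.shape}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    flips = rng.random(3) < prob
    arrays = (m, f) + extras

    def do(a):
        for ax, flip in enumerate(flips):
            if flip:
                a = np.flip(a, axis=a.ndim - 3 + ax)
        return np.ascontiguousarray(a)

    out = tuple(do(a) for a in arrays)
    return out if extras else out[:2]


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(path, model: WaveMorph, run_config: RunConfig | None = None,
                    meta: dict | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {f"param__{k}": v for k, v in model.state_dict().items()}
    cfg = run_config.to_dict() if run_config is not None \
        else {"model": model.config.to_dict()}
    payload["config_json"] = np.frombuffer(
        json.dumps({"config": cfg, "meta": meta or {}}).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[WaveMorph, dict, dict]:
    """Returns (model with restored weights, run-config dict, meta dict)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no checkpoint at {path}")
    with np.load(path) as z:
        blob = json.loads(bytes(z["config_json"]).decode())
        state = {k[len("param__"):]: z[k] for k in z.files
                 if k.startswith("param__")}
    cfg = blob["config"]
    model = WaveMorph(ModelConfig.from_dict(cfg["model"]))
    model.load_state_dict(state)
    return model, cfg, blob.get("meta", {})


# -- pair normalization ----------------------------------------------------

def _as_pair(p):
    """Normalize a pair spec to (moving, fixed, moving_labels, fixed_labels)."""
    if isinstance(p, SynthPair):
        return (p.moving.intensity, p.fixed.intensity,
                p.moving.labels, p.fixed.labels)
    if isinstance(p, dict):
        return (p["moving"], p["fixed"],
                p.get("moving_labels"), p.get("fixed_labels"))
    if len(p) == 2:
        return p[0], p[1], None, None
    if len(p) == 4:
        return tuple(p)
    raise TypeError(f"cannot interpret pair spec of type {type(p)}")


# -- training --------------------------------------------------------------

def _predict_field(model: WaveMorph, m: np.ndarray, f: np.ndarray) -> np.ndarray:
    mp, crop = pad_to_multiple(m.astype(np.float32), model.required_multiple)
    fp, _ = pad_to_multiple(f.astype(np.float32), model.required_multiple)
    u = model.predict(mp, fp)
    return u[(slice(None),) + crop]


def _eval_pairs(model: WaveMorph, pairs) -> tuple[float, float]:
    """Mean hierarchical Dice and mean folding ratio over labelled pairs."""
    rows, frs = [], []
    for idx, p in enumerate(pairs):
        m, f, mlab, flab = _as_pair(p)
        u = _predict_field(model, m, f)
        frs.append(folding_ratio(u))
        if mlab is not None and flab is not None:
            warped = warp(mlab, u, mode="nearest")
            for s, d in dice_per_structure(warped, flab).items():
                rows.append({"pair": idx, "structure": s, "dice": d})
    mean_dice = summarize_dice(pd.DataFrame(rows))[0] if rows else float("nan")
    return mean_dice, float(np.mean(frs))


def train(config: RunConfig, pairs, val_pairs=None, out_dir=None,
          max_steps: int | None = None, resume=None,
          log_fn=None) -> dict:
    """Optimize the registration network on a list of image pairs.

    Returns a result dict with the trained ``model``, per-epoch ``history``,
    ``val_history``, ``best_val_dice`` and (if ``out_dir`` is given) the
    ``checkpoint`` path of the best-validation-Dice weights.  Aborts with a
    diagnostic if the similarity or regularization term goes non-finite.
    """
    pairs = [_as_pair(p) for p in pairs]
    if not pairs:
        raise ValueError("no training pairs given")
    if resume is not None:
        model, _, _ = load_checkpoint(resume)
    else:
        model = WaveMorph(config.model, seed=config.seed)
    opt = Adam(model.parameters(), lr=config.lr)
    aug_rng = np.random.default_rng(config.seed + 1)

    history, val_history = [], []
    best = {"dice": -np.inf, "epoch": -1}
    out_dir = Path(out_dir) if out_dir is not None else None
    ckpt_path = out_dir / "checkpoint_best.npz" if out_dir else None
    step = 0
    stop = False
    for epoch in range(config.epochs):
        ep_loss, ep_sim, ep_reg, nb = 0.0, 0.0, 0.0, 0
        for m, f, mlab, flab in pairs:
            if config.flip_augment > 0:
                m, f = augment_flip(m, f, config.flip_augment, aug_rng)
            mp, crop = pad_to_multiple(m.astype(np.float32),
                                       model.required_multiple)
            fp, _ = pad_to_multiple(f.astype(np.float32),
                                    model.required_multiple)
            mt = Tensor(mp[None, None])
            ft = Tensor(fp[None, None])
            u_pad = model(mt, ft)
            u = u_pad[(slice(None), slice(None)) + crop]
            loss, sim, reg = total_loss(Tensor(f[None, None].astype(np.float32)),
                                        Tensor(m[None, None].astype(np.float32)),
                                        u, config.loss)
            for name, t in (("similarity", sim), ("regularization", reg)):
                if not np.isfinite(t.item()):
                    raise RuntimeError(
                        f"non-finite {name} term ({t.item()}) at epoch "
                        f"{epoch}, step {step}; aborting")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += loss.item()
            ep_sim += sim.item()
            ep_reg += reg.item()
            nb += 1
            step += 1
            if max_steps is not None and step >= max_steps:
                stop = True
                break
        entry = {"epoch": epoch, "step": step, "loss": ep_loss / nb,
                 "sim": ep_sim / nb, "reg": ep_reg / nb}
        history.append(entry)
        if log_fn:
            log_fn(entry)
        last_epoch = stop or epoch == config.epochs - 1
        if val_pairs and (last_epoch or (epoch + 1) % config.val_interval == 0):
            vdice, vfr = _eval_pairs(model, val_pairs)
            val_history.append({"epoch": epoch, "dice": vdice, "fr": vfr})
            if log_fn:
                log_fn(val_history[-1])
            if np.isfinite(vdice) and vdice > best["dice"]:
                best = {"dice": vdice, "epoch": epoch}
                if ckpt_path:
                    save_checkpoint(ckpt_path, model, config,
                                    meta={"epoch": epoch, "val_dice": vdice})
        if stop:
            break
    if ckpt_path and best["epoch"] < 0:
        save_checkpoint(ckpt_path, model, config, meta={"epoch": history[-1]["epoch"]})
    return {"model": model, "history": history, "val_history": val_history,
            "best_val_dice": best["dice"] if best["epoch"] >= 0 else None,
            "checkpoint": ckpt_path}


def instance_refine(model: WaveMorph, moving: np.ndarray, fixed: np.ndarray,
                    loss: LossConfig | None = None, *, lr: float = 3e-3,
                    steps: int = 50) -> np.ndarray:
    """Instance-specific optimization: fine-tune a copy of the model on one
    pair with the unsupervised loss and return the refined field.

    The amortize-then-optimize protocol of deformable registration: the
    trained network supplies a warm start and strong prior, and a short
    per-pair optimization (no labels involved) closes the remaining gap.
    The supplied model is left untouched.
    """
    loss = loss or LossConfig()
    state = model.state_dict()
    try:
        opt = Adam(model.parameters(), lr=lr)
        mp, crop = pad_to_multiple(moving.astype(np.float32),
                                   model.required_multiple)
        fp, _ = pad_to_multiple(fixed.astype(np.float32),
                                model.required_multiple)
        mt = Tensor(mp[None, None])
        ft = Tensor(fp[None, None])
        m_orig = Tensor(moving[None, None].astype(np.float32))
        f_orig = Tensor(fixed[None, None].astype(np.float32))
        for _ in range(steps):
            u = model(mt, ft)[(slice(None), slice(None)) + crop]
            total, sim, reg = total_loss(f_orig, m_orig, u, loss)
            if not np.isfinite(total.item()):
                raise RuntimeError("non-finite loss during instance refinement")
            opt.zero_grad()
            total.backward()
            opt.step()
        return _predict_field(model, moving, fixed)
    finally:
        model.load_state_dict(state)


# -- inference and evaluation ----------------------------------------------

def register(checkpoint, moving_path, fixed_path, out_dir,
             moving_labels_path=None) -> dict:
    """Register one NIfTI pair with a trained model.

    Writes ``warped.nii.gz`` and ``field.nii.gz`` (and ``warped_seg.nii.gz``
    when labels are supplied) to ``out_dir``; returns their paths plus the
    field's folding ratio.
    """
    model = checkpoint if isinstance(checkpoint, WaveMorph) \
        else load_checkpoint(checkpoint)[0]
    moving, aff_m = read_nifti(moving_path)
    fixed, aff_f = read_nifti(fixed_path)
    if moving.shape != fixed.shape:
        raise ValueError(f"moving {moving.shape} and fixed {fixed.shape} "
                         "shapes differ")
    if not np.allclose(aff_m, aff_f, atol=1e-5):
        raise ValueError("moving and fixed affines differ; resample first")
    u = _predict_field(model, np.asarray(moving, np.float32),
                       np.asarray(fixed, np.float32))
    warped = warp(np.asarray(moving, np.float32), u)
    out_dir = Path(out_dir)
    paths = {"warped": out_dir / "warped.nii.gz",
             "field": out_dir / "field.nii.gz"}
    write_nifti(warped, paths["warped"], aff_m)
    write_nifti(u, paths["field"], aff_m)
    if moving_labels_path is not None:
        labels, _ = read_nifti(moving_labels_path)
        paths["warped_seg"] = out_dir / "warped_seg.nii.gz"
        write_nifti(warp(labels, u, mode="nearest"), paths["warped_seg"], aff_m)
    return {"paths": paths, "folding_ratio": folding_ratio(u)}


def evaluate(checkpoint, pairs_with_labels, out_dir=None) -> dict:
    """Per-pair, per-structure Dice and folding ratios for labelled pairs.

    Returns {"table": DataFrame(pair, structure, dice), "summary": {...}};
    writes ``dice.csv`` and ``summary.json`` when ``out_dir`` is given.
    """
    model = checkpoint if isinstance(checkpoint, WaveMorph) \
        else load_checkpoint(checkpoint)[0]
    rows, frs = [], []
    for idx, p in enumerate(pairs_with_labels):
        m, f, mlab, flab = _as_pair(p)
        if mlab is None or flab is None:
            raise ValueError(f"pair {idx} lacks label maps; evaluation "
                             "requires segmentations")
        u = _predict_field(model, m, f)
        frs.append(folding_ratio(u))
        warped = warp(mlab, u, mode="nearest")
        for s, d in dice_per_structure(warped, flab).items():
            rows.append({"pair": idx, "structure": s, "dice": d})
    table = pd.DataFrame(rows)
    dmean, dsd = summarize_dice(table)
    summary = {"dice_mean": dmean, "dice_sd": dsd,
               "fr_mean": float(np.mean(frs)), "fr_sd": float(np.std(frs))}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "dice.csv", index=False)
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return {"table": table, "summary": summary}
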