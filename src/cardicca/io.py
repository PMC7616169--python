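"""Manifests, HDF5 array containers, checkpoints and provenance.

On-disk layout:

* **Manifest** — CSV with columns ``subject_id, label, view1_frames,
  view1_es, view2_frames, view2_es`` (labels: 0 = non-responder,
  1 = responder); row order is preserved everywhere.
* **Array container** — HDF5 keyed ``/subjects/<id>/<view>/frames`` for native
  latent sequences (``(n_frames, d)``; ``es_index`` as an attribute) and
  ``/subjects/<id>/<view>/matrix`` for canonical d x T matrices.  The root
  carries the subject order, generator config (JSON) and provenance.
* **DCCA checkpoint** — HDF5 with both branches' parameter arrays, the
  post-hoc CCA, the training curve and hyperparameters, plus a JSON sidecar
  of the hyperparameters; the SVM head is pickled alongside.

Every writer embeds the config hash and seed that produced the artifact.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .cca import CCAResult
from .cohort import CohortConfig, SubjectRecord  # noqa: F401  (re-export context)
from .dcca import DeepCCA
from .exceptions import ValidationError
from .preprocessing import CycleTimings, LatentMatrix, View

__all__ = ["config_hash", "write_manifest", "read_manifest", "write_cohort",
           "read_cohort", "write_matrices", "read_matrices",
           "save_dcca_checkpoint", "load_dcca_checkpoint",
           "save_classifier", "load_classifier"]

MANIFEST_COLUMNS = ["subject_id", "label", "view1_frames", "view1_es",
                    "view2_frames", "view2_es"]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def write_manifest(cohort: list[SubjectRecord], path) -> None:
    rows = [{
        "subject_id": s.subject_id,
        "label": s.label,
        "view1_frames": s.timings_view1.n_frames,
        "view1_es": s.timings_view1.es_index,
        "view2_frames": s.timings_view2.n_frames,
        "view2_es": s.timings_view2.es_index,
    } for s in cohort]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path) -> list[dict]:
    """Read and validate a manifest; returns per-subject stub dicts in row order."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest {path}: missing columns {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        row = int(dup.index[0]) + 2  # 1-based with header
        raise ValidationError(
            f"manifest {path}: duplicate subject_id {dup.iloc[0]!r} at row {row}")
    stubs = []
    for i, row in df.iterrows():
        try:
            stubs.append({
                "subject_id": str(row["subject_id"]),
                "label": int(row["label"]),
                "timings_view1": CycleTimings(0, int(row["view1_es"]),
                                              int(row["view1_frames"])),
                "timings_view2": CycleTimings(0, int(row["view2_es"]),
                                              int(row["view2_frames"])),
            })
        except (ValueError, ValidationError) as exc:
            raise ValidationError(
                f"manifest {path}: invalid row {int(i) + 2}: {exc}") from None
    return stubs


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

def write_cohort(cohort: list[SubjectRecord], container_path,
                 manifest_path=None, config: CohortConfig | None = None,
                 seed: int | None = None) -> None:
    with h5py.File(container_path, "w") as f:
        f.attrs["subject_ids"] = json.dumps([s.subject_id for s in cohort])
        f.attrs["cardicca_version"] = __version__
        if config is not None:
            cfg = config.to_dict()
            f.attrs["cohort_config"] = json.dumps(cfg, sort_keys=True)
            f.attrs["config_hash"] = config_hash(cfg)
        if seed is not None:
            f.attrs["seed"] = int(seed)
        for s in cohort:
            grp = f.create_group(f"subjects/{s.subject_id}")
            grp.attrs["label"] = s.label
            for view, frames, timings in (
                    ("view1", s.view1_frames, s.timings_view1),
                    ("view2", s.view2_frames, s.timings_view2)):
                ds = grp.create_dataset(f"{view}/frames", data=frames)
                ds.attrs["es_index"] = timings.es_index
    if manifest_path is not None:
        write_manifest(cohort, manifest_path)


def read_cohort(container_path) -> list[SubjectRecord]:
    with h5py.File(container_path, "r") as f:
        ids = json.loads(f.attrs["subject_ids"])
        cohort = []
        for sid in ids:
            grp = f[f"subjects/{sid}"]
            frames, timings = {}, {}
            for view in ("view1", "view2"):
                ds = grp[f"{view}/frames"]
                arr = ds[()]
                frames[view] = arr
                timings[view] = CycleTimings(0, int(ds.attrs["es_index"]),
                                             arr.shape[0])
            cohort.append(SubjectRecord(
                subject_id=sid, label=int(grp.attrs["label"]),
                view1_frames=frames["view1"], view2_frames=frames["view2"],
                timings_view1=timings["view1"], timings_view2=timings["view2"]))
    return cohort


def write_matrices(matrices: list[LatentMatrix], container_path) -> None:
    """Store canonical latent matrices under /subjects/<id>/<view>/matrix."""
    with h5py.File(container_path, "a") as f:
        for m in matrices:
            key = f"subjects/{m.subject_id}/{m.view_tag.value}/matrix"
            if key in f:
                del f[key]
            ds = f.create_dataset(key, data=m.values)
            ds.attrs["T"] = m.T
            ds.attrs["view_tag"] = m.view_tag.value


def read_matrices(container_path, view: View | str) -> list[LatentMatrix]:
    view = View(view)
    out = []
    with h5py.File(container_path, "r") as f:
        for sid in json.loads(f.attrs["subject_ids"]):
            key = f"subjects/{sid}/{view.value}/matrix"
            if key not in f:
                raise ValidationError(
                    f"{container_path}: no canonical matrix for subject {sid} "
                    f"{view.value}; run the resample stage first")
            out.append(LatentMatrix(values=f[key][()], view_tag=view,
                                    subject_id=sid))
    return out


# ---------------------------------------------------------------------------
# model checkpoints
# ---------------------------------------------------------------------------

def save_dcca_checkpoint(model: DeepCCA, path, sidecar_path=None) -> None:
    hyper = {"k_dcca": model.k_dcca, "learning_rate": model.learning_rate,
             "epochs": model.epochs, "batch_size": model.batch_size,
             "cov_reg": model.cov_reg, "k_corr": model.k_corr_,
             "linear_probe": model.linear_probe,
             "minibatch_loss": model.minibatch_loss, "seed": model.seed}
    with h5py.File(path, "w") as f:
        f.attrs["hyperparams"] = json.dumps(hyper, sort_keys=True)
        f.attrs["cardicca_version"] = __version__
        f.create_dataset("training_curve", data=model.training_curve_)
        f.attrs["objective"] = model.objective_
        for name, branch in (("branch1", model.branch1_),
                             ("branch2", model.branch2_)):
            for i, p in enumerate(branch.params):
                f.create_dataset(f"{name}/p{i:03d}", data=p)
        cca = model.post_cca_
        g = f.create_group("post_cca")
        for key in ("projection_1", "projection_2", "mean_1", "mean_2",
                    "correlations"):
            g.create_dataset(key, data=getattr(cca, key))
        g.attrs["reg"] = cca.reg
    if sidecar_path is not None:
        Path(sidecar_path).write_text(json.dumps(hyper, indent=2, sort_keys=True))


def load_dcca_checkpoint(path) -> DeepCCA:
    with h5py.File(path, "r") as f:
        hyper = json.loads(f.attrs["hyperparams"])
        k_corr = hyper.pop("k_corr")
        model = DeepCCA(**hyper)
        # rebuild branches with the stored weights; input channel counts are
        # recoverable from the first conv weight
        import numpy as _np
        from . import nn as _nn
        rng = _np.random.default_rng(hyper["seed"])
        branches = []
        for name in ("branch1", "branch2"):
            keys = sorted(k for k in f[name])
            weights = [f[name][k][()] for k in keys]
            in_ch = weights[0].shape[1]
            branch = _nn.build_branch(hyper["k_dcca"], rng,
                                      hyper["linear_probe"], in_ch)
            branch.set_weights(weights)
            branches.append(branch)
        model.branch1_, model.branch2_ = branches
        g = f["post_cca"]
        model.post_cca_ = CCAResult(
            projection_1=g["projection_1"][()], projection_2=g["projection_2"][()],
            mean_1=g["mean_1"][()], mean_2=g["mean_2"][()],
            correlations=g["correlations"][()], reg=float(g.attrs["reg"]))
        model.training_curve_ = f["training_curve"][()]
        model.objective_ = float(f.attrs["objective"])
        model.k_corr_ = k_corr
        model.n_features_in_ = None
    return model


def save_classifier(clf, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(clf, fh)


def load_classifier(path):
    with open(path, "rb") as fh:
        return pickle.load(fh)
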