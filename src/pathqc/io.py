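"""Shared I/O: manifests, embedding tables, model bundles, run configuration.

All tabular outputs are UTF-8 tab-delimited text with a header row and the
empty string for missing values, so every artifact can be consumed directly
from R or a spreadsheet. Model bundles are directories holding a JSON
metadata file plus a ``.npz`` archive of numeric arrays.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tissue_models import QualityModel, SlideRecord

BUNDLE_VERSION = 1

MANIFEST_COLUMNS = [
    "slide_id", "donor_id", "tissue", "rin", "autolysis", "hardy", "age", "sex",
]

__all__ = [
    "MANIFEST_COLUMNS",
    "RunConfig",
    "read_manifest",
    "write_manifest",
    "read_embeddings",
    "write_embeddings",
    "save_bundle",
    "load_bundle",
    "write_run_log",
]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the published operating point.

    512x512 patches, at most 50% background per patch, at least 2 valid
    patches per slide, 5 CV folds, 70:30 train-test split, top-5% feature
    screening, 500 classifier features, routing confidence threshold 0.6.
    """

    patch_size: int = 512
    max_background_fraction: float = 0.5
    min_valid_patches: int = 2
    encoder: str = "synthetic"
    encoder_dim: int = 1024
    n_folds: int = 5
    test_fraction: float = 0.3
    top_feature_fraction: float = 0.05
    pan_k: int = 500
    confidence_threshold: float = 0.6
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls(**payload)


def _parse_field(value: str, kind: str):
    if value == "" or value is None:
        return None
    if kind == "float":
        return float(value)
    if kind == "int":
        return int(float(value))
    return str(value)


_FIELD_KINDS = {
    "rin": "float", "autolysis": "int", "hardy": "int", "age": "float",
    "sex": "str",
}


def read_manifest(path: str | Path) -> list[SlideRecord]:
    """Read a tab-delimited slide manifest into typed records.

    Empty fields become missing values; duplicate slide ids are an error;
    a malformed row raises with its line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = {"slide_id", "donor_id", "tissue"} - set(df.columns)
    if missing_cols:
        raise ValueError(f"manifest missing required columns: {sorted(missing_cols)}")
    dupes = df["slide_id"][df["slide_id"].duplicated()].unique()
    if dupes.size:
        raise ValueError(f"duplicate slide_id values: {list(dupes[:5])}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        row = row._asdict()
        try:
            records.append(
                SlideRecord(
                    slide_id=row["slide_id"],
                    donor_id=row["donor_id"],
                    tissue=row["tissue"],
                    **{
                        k: _parse_field(row.get(k, ""), kind)
                        for k, kind in _FIELD_KINDS.items()
                    },
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed manifest row at line {i}: {exc}") from exc
    return records


def write_manifest(records: list[SlideRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {k: ("" if getattr(r, k) is None else getattr(r, k)) for k in MANIFEST_COLUMNS}
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def write_embeddings(slide_ids, X: np.ndarray, path: str | Path) -> None:
    """Write a slide-embedding matrix: first column slide_id, then the 4d
    feature columns named mean_0001..max_{d}."""
    from .embed import feature_names

    X = np.asarray(X, dtype=float)
    d4 = X.shape[1]
    if d4 % 4:
        raise ValueError("embedding width must be a multiple of 4")
    df = pd.DataFrame(X, columns=feature_names(d4 // 4))
    df.insert(0, "slide_id", list(slide_ids))
    df.to_csv(path, sep="\t", index=False)


def read_embeddings(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "slide_id":
        raise ValueError("first embedding column must be slide_id")
    return df["slide_id"].astype(str).tolist(), df.iloc[:, 1:].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# model bundles


def _quality_model_arrays(model: QualityModel) -> dict[str, np.ndarray]:
    return {
        "feature_means": model.feature_means,
        "feature_sds": model.feature_sds,
        "selected_features": model.selected_features,
        "coefficients": model.coefficients,
    }


def _quality_model_meta(model: QualityModel) -> dict:
    return {
        "tissue": model.tissue,
        "target": model.target,
        "intercept": model.intercept,
        "lambda": model.lambda_,
        "alpha": model.alpha,
        "n_training_slides": model.n_training_slides,
        "fold_correlations": list(map(float, model.fold_correlations)),
    }


def _rebuild_quality_model(meta: dict, arrays, prefix: str = "") -> QualityModel:
    return QualityModel(
        tissue=meta["tissue"],
        target=meta["target"],
        feature_means=arrays[prefix + "feature_means"],
        feature_sds=arrays[prefix + "feature_sds"],
        selected_features=arrays[prefix + "selected_features"],
        coefficients=arrays[prefix + "coefficients"],
        intercept=float(meta["intercept"]),
        lambda_=float(meta["lambda"]),
        alpha=float(meta["alpha"]),
        n_training_slides=int(meta.get("n_training_slides", 0)),
        fold_correlations=list(meta.get("fold_correlations", [])),
    )


def save_bundle(model, path: str | Path) -> None:
    """Serialize a fitted QualityModel or PanTissueModel to a directory.

    The bundle holds ``meta.json`` (configuration, fitted scalars including
    the selected penalty, library versions) and ``arrays.npz``.
    """
    from .pan_tissue import PanTissueModel

    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    versions = {"numpy": np.__version__, "python": platform.python_version()}

    if isinstance(model, QualityModel):
        meta = {
            "bundle_version": BUNDLE_VERSION,
            "kind": "quality_model",
            "versions": versions,
            "model": _quality_model_meta(model),
        }
        arrays = _quality_model_arrays(model)
    elif isinstance(model, PanTissueModel):
        import sklearn

        versions["scikit-learn"] = sklearn.__version__
        clf = model.classifier
        meta = {
            "bundle_version": BUNDLE_VERSION,
            "kind": "pan_tissue_model",
            "versions": versions,
            "confidence_threshold": model.confidence_threshold,
            "classifier": {
                "C": clf.C,
                "cv_accuracy": clf.cv_accuracy,
                "cv_deviance": clf.cv_deviance,
                "classes": [str(c) for c in clf.classes],
            },
            "registry": {
                tissue: {
                    target: _quality_model_meta(qm)
                    for target, qm in per_target.items()
                }
                for tissue, per_target in model.tissue_registry.items()
            },
        }
        arrays = {
            "selected_features": model.selected_features,
            "clf_coef": clf.model.coef_,
            "clf_intercept": clf.model.intercept_,
            "clf_feature_means": clf.feature_means,
            "clf_feature_sds": clf.feature_sds,
        }
        for tissue, per_target in model.tissue_registry.items():
            for target, qm in per_target.items():
                for key, arr in _quality_model_arrays(qm).items():
                    arrays[f"registry/{tissue}/{target}/{key}"] = arr
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")

    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    np.savez(out / "arrays.npz", **arrays)


def load_bundle(path: str | Path):
    """Load a model bundle written by :func:`save_bundle`.

    Raises on a missing/truncated archive or a bundle-version mismatch;
    there is no silent fallback.
    """
    from sklearn.linear_model import LogisticRegression

    from .pan_tissue import PanTissueModel, TissueClassifier

    root = Path(path)
    meta_path, arrays_path = root / "meta.json", root / "arrays.npz"
    if not meta_path.exists() or not arrays_path.exists():
        raise FileNotFoundError(f"bundle at {root} is missing meta.json or arrays.npz")
    try:
        meta = json.loads(meta_path.read_text())
        arrays = dict(np.load(arrays_path))
    except Exception as exc:
        raise ValueError(f"bundle at {root} is corrupt or truncated: {exc}") from exc
    if meta.get("bundle_version") != BUNDLE_VERSION:
        raise ValueError(
            f"bundle version {meta.get('bundle_version')} != supported {BUNDLE_VERSION}"
        )

    if meta["kind"] == "quality_model":
        return _rebuild_quality_model(meta["model"], arrays)
    if meta["kind"] == "pan_tissue_model":
        clf_meta = meta["classifier"]
        try:
            lr = LogisticRegression(l1_ratio=1.0, C=clf_meta["C"], solver="saga")
        except TypeError:
            lr = LogisticRegression(penalty="l1", C=clf_meta["C"], solver="saga")
        lr.coef_ = arrays["clf_coef"]
        lr.intercept_ = arrays["clf_intercept"]
        lr.classes_ = np.array(clf_meta["classes"])
        lr.n_features_in_ = arrays["clf_coef"].shape[1]
        classifier = TissueClassifier(
            model=lr,
            feature_means=arrays["clf_feature_means"],
            feature_sds=arrays["clf_feature_sds"],
            C=float(clf_meta["C"]),
            cv_accuracy=float(clf_meta["cv_accuracy"]),
            cv_deviance=float(clf_meta["cv_deviance"]),
        )
        registry = {
            tissue: {
                target: _rebuild_quality_model(
                    qmeta, arrays, prefix=f"registry/{tissue}/{target}/"
                )
                for target, qmeta in per_target.items()
            }
            for tissue, per_target in meta["registry"].items()
        }
        return PanTissueModel(
            selected_features=arrays["selected_features"],
            classifier=classifier,
            tissue_registry=registry,
            confidence_threshold=float(meta["confidence_threshold"]),
        )
    raise ValueError(f"unknown bundle kind {meta['kind']!r}")


def write_run_log(out_dir: str | Path, config: dict, seed: int | None = None) -> Path:
    """Write a machine-readable log of a CLI run (config, seed, versions)."""
    import sklearn
    import scipy
    import skimage

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = {
        "config": config,
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "scikit-image": skimage.__version__,
        },
    }
    path = out / "run_log.json"
    path.write_text(json.dumps(log, indent=2))
    return path
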