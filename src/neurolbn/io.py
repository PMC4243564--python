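"""File formats and the end-to-end pipeline driver.

Formats (all UTF-8, comma-separated, headered; floats written with 17
significant digits so round-trips are lossless):

* annotations.csv — neuron_id, annotator_id, characterized, C1..C5; one
  row per (neuron, annotator).
* features.csv    — neuron_id, X1..X18.
* metadata.csv    — neuron_id, thickness_lo_um, thickness_hi_um,
  column_diameter_um, vertical_axis, depth_axis.
* lbns.json       — {neuron_id: serialized BayesianNetwork}.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .bayesnet import BayesianNetwork
from .labels import (
    DEFAULT_SCHEMA,
    AnnotationMatrix,
    NomenclatureSchema,
    apply_c4_rule,
    filter_characterized,
    learn_lbn,
)
from .morphometry import (
    FEATURE_NAMES,
    NeuronMetadata,
    compute_features,
    parse_swc,
)

__all__ = [
    "read_annotations",
    "write_annotations",
    "read_features",
    "write_features",
    "read_metadata",
    "write_metadata",
    "read_lbns",
    "write_lbns",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"
_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_bool(value: str, where: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"{where}: cannot parse characterized flag {value!r}")


def read_annotations(path, schema: NomenclatureSchema = DEFAULT_SCHEMA
                     ) -> list[AnnotationMatrix]:
    """One AnnotationMatrix per neuron_id, row order preserved."""
    df = pd.read_csv(path, dtype=str)
    required = ["neuron_id", "annotator_id", "characterized", *schema.names]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    dup = df.duplicated(subset=["neuron_id", "annotator_id"])
    if dup.any():
        i = int(df.index[dup][0])
        raise ValueError(
            f"{path}: duplicate (neuron, annotator) pair at row {i + 2}"
        )
    for row_pos, (_, row) in enumerate(df.iterrows()):
        char = _parse_bool(row["characterized"], f"{path}: row {row_pos + 2}")
        if not char:
            continue
        for name in schema.names:
            val = row[name]
            if pd.isna(val):
                continue
            if val not in schema.variable(name).categories:
                raise ValueError(
                    f"{path}: row {row_pos + 2}: value {val!r} is not a "
                    f"category of {name}"
                )
    df["characterized"] = [
        _parse_bool(v, path) for v in df["characterized"]
    ]
    df.loc[~df["characterized"], list(schema.names)] = pd.NA
    matrices = []
    for nid in df["neuron_id"].drop_duplicates():
        sub = df[df["neuron_id"] == nid].drop(columns=["neuron_id"])
        matrices.append(AnnotationMatrix(str(nid), sub.reset_index(drop=True),
                                         schema=schema))
    return matrices


def write_annotations(matrices, path) -> None:
    frames = []
    for m in matrices:
        df = m.rows.copy()
        df.insert(0, "neuron_id", m.neuron_id)
        frames.append(df[["neuron_id", "annotator_id", "characterized",
                          *m.schema.names]])
    out = pd.concat(frames, ignore_index=True)
    out["characterized"] = out["characterized"].map({True: "true", False: "false"})
    out.to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("neuron_id", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df.set_index("neuron_id")


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, float_format=_FLOAT_FMT,
                    index_label="neuron_id")


def read_metadata(path) -> list[NeuronMetadata]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        out.append(NeuronMetadata(
            neuron_id=str(row["neuron_id"]),
            thickness_lo_um=float(row["thickness_lo_um"]),
            thickness_hi_um=float(row["thickness_hi_um"]),
            column_diameter_um=float(row.get("column_diameter_um", 300.0)),
            vertical_axis=str(row.get("vertical_axis", "y")),
            depth_axis=str(row.get("depth_axis", "z")),
        ))
    return out


def write_metadata(metadata, path) -> None:
    pd.DataFrame([asdict(m) for m in metadata]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_lbns(path) -> dict[str, BayesianNetwork]:
    with open(path) as fh:
        raw = json.load(fh)
    return {nid: BayesianNetwork.from_dict(d) for nid, d in raw.items()}


def write_lbns(lbns: dict[str, BayesianNetwork], path) -> None:
    with open(path, "w") as fh:
        json.dump({nid: bn.to_dict() for nid, bn in lbns.items()}, fh, indent=1)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths and settings for the extract -> learn-lbns -> evaluate run."""

    annotations: str
    out_dir: str
    swc_dir: str | None = None
    metadata: str | None = None
    features: str | None = None  # skip extraction when given
    k: int = 7
    score: str = "bde"
    ess: float = 1.0
    per_param: int = 500
    repetitions: int = 20
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2 (the weight formula divides by k-1)")
        if self.features is None and (self.swc_dir is None or self.metadata is None):
            raise ValueError("need either a features CSV or swc_dir + metadata")

    def to_dict(self) -> dict:
        return asdict(self)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns {artifact name: path}.

    Stages: (1) extract features from SWC reconstructions (unless a
    features CSV is supplied), (2) filter annotation matrices, apply the
    C4 rule and learn one LBN per neuron, (3) cross-validate the
    consensus classifier and write the evaluation report.  A manifest
    with the config hash makes any output reproducible.
    """
    from .evaluation import CvPlan, cross_validate

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    # -- stage 1: features -------------------------------------------------
    try:
        if config.features is not None:
            features = read_features(config.features)
        else:
            metadata = {m.neuron_id: m for m in read_metadata(config.metadata)}
            rows = {}
            for nid, meta in metadata.items():
                recon = parse_swc(Path(config.swc_dir) / f"{nid}.swc")
                rows[nid] = compute_features(recon, meta).values
            features = pd.DataFrame.from_dict(
                rows, orient="index", columns=list(FEATURE_NAMES)
            )
            features.index.name = "neuron_id"
        fpath = out / "features.csv"
        write_features(features, fpath)
        artifacts["features"] = str(fpath)
        log.info("stage extract: %d neurons, %d features", *features.shape)
    except Exception as exc:
        raise RuntimeError(f"stage 'extract-features' failed: {exc}") from exc

    # -- stage 2: LBNs -----------------------------------------------------
    try:
        matrices = read_annotations(config.annotations)
        kept = []
        for m in matrices:
            filtered, excluded = filter_characterized(m)
            if excluded:
                log.info("neuron %s excluded (uncharacterized majority)", m.neuron_id)
                continue
            kept.append(apply_c4_rule(filtered))
        lbns = {
            m.neuron_id: learn_lbn(m, score=config.score, ess=config.ess,
                                   seed=config.seed)
            for m in kept
        }
        lpath = out / "lbns.json"
        write_lbns(lbns, lpath)
        artifacts["lbns"] = str(lpath)
        log.info("stage learn-lbns: %d networks", len(lbns))
    except Exception as exc:
        raise RuntimeError(f"stage 'learn-lbns' failed: {exc}") from exc

    # -- stage 3: evaluation -----------------------------------------------
    try:
        ids = [m.neuron_id for m in kept if m.neuron_id in features.index]
        if len(ids) < config.folds:
            raise ValueError("fewer aligned neurons than CV folds")
        X = features.loc[ids, list(FEATURE_NAMES)].to_numpy(dtype=float)
        mats = [m for m in kept if m.neuron_id in features.index]
        report = cross_validate(
            X, mats, [lbns[i] for i in ids], k=config.k,
            plan=CvPlan(config.repetitions, config.folds, config.seed),
            score=config.score, ess=config.ess, per_param=config.per_param,
        )
        rpath = out / "report.json"
        with open(rpath, "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        artifacts["report"] = str(rpath)
    except Exception as exc:
        raise RuntimeError(f"stage 'evaluate' failed: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "artifacts": artifacts,
    }
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1)
    artifacts["manifest"] = str(mpath)
    return artifacts
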