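"""Synthetic study generator: archetypes, annotations, morphologies, features.

Every stage of the classification pipeline is testable without any
external download by emulating the study conditions: a panel of
annotators labels each neuron, neurons fall into a small number of
morphological *archetypes*, and the 18 morphometric predictors of
same-archetype neurons cluster in feature space.

* ``generate_archetypes`` draws random label Bayesian networks over the
  interneuron nomenclature (sparse DAGs, peaked Dirichlet CPT rows).
* ``generate_annotations`` simulates an annotator panel: each row is drawn
  from the mixture (1 - ambiguity) * p_archetype + ambiguity * uniform,
  then made consistent with the C4 "no" rule.
* ``generate_neuron_swc`` grows a branching-random-walk axon whose
  vertical drift, lateral spread and total length are biased per
  archetype, yielding systematic differences in X6..X18.
* ``generate_study`` assembles the coherent end-to-end fixture (SWC files,
  metadata, annotation matrices, feature vectors, learned LBNs).

Feature vectors follow a Gaussian cluster model: archetype centroids sit
at the vertices of a randomly rotated regular simplex whose edge length is
``feature_separation`` in units of the within-cluster radial sd (the
c-separation convention for Gaussian mixtures), with unit per-feature
noise.  At separation >= 3 same-archetype neurons are mutual near
neighbors after standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import ortho_group

from .bayesnet import BayesianNetwork, Cpt, DagStructure, VariableSpec, logic_sample
from .labels import (
    DEFAULT_SCHEMA,
    AnnotationMatrix,
    NomenclatureSchema,
    learn_lbn,
)
from .morphometry import FEATURE_NAMES, NeuronMetadata, Reconstruction, SwcPoint

__all__ = [
    "SyntheticStudyConfig",
    "SyntheticStudy",
    "generate_archetypes",
    "generate_annotations",
    "generate_neuron_swc",
    "generate_study",
]

_C4_DIRECTIONAL = ("ascending", "descending", "both")


@dataclass
class SyntheticStudyConfig:
    """Knobs of the synthetic study; defaults emulate the real panel.

    ``ambiguity`` mixes a uniform contaminant into each annotator's label
    distribution; ``feature_separation`` is the between-archetype centroid
    distance in within-cluster radial sd units.
    """

    n_archetypes: int = 5
    n_neurons: int = 200
    annotators_per_neuron: int = 42
    ambiguity: float = 0.1
    feature_separation: float = 4.0
    uncharacterized_fraction: float = 0.0
    cpt_concentration: float = 0.05
    arc_probability: float = 0.3
    max_parents: int = 2
    seed: int = 0
    schema: NomenclatureSchema = field(default=DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        if min(self.n_archetypes, self.n_neurons, self.annotators_per_neuron) < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.ambiguity <= 1:
            raise ValueError("ambiguity must be in [0, 1]")
        if not 0 <= self.uncharacterized_fraction < 1:
            raise ValueError("uncharacterized_fraction must be in [0, 1)")


def _seq(config: SyntheticStudyConfig, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, *key])


def generate_archetypes(config: SyntheticStudyConfig) -> list[BayesianNetwork]:
    """Random archetype LBNs: sparse DAGs with Dirichlet CPT rows."""
    rng = np.random.default_rng(_seq(config, 1))
    schema = config.schema
    names = schema.names
    archetypes = []
    for _ in range(config.n_archetypes):
        parents: dict[str, list[str]] = {n: [] for n in names}
        arcs = set()
        for j, child in enumerate(names):
            for parent in names[:j]:
                if len(parents[child]) >= config.max_parents:
                    break
                if rng.random() < config.arc_probability:
                    parents[child].append(parent)
                    arcs.add((parent, child))
        structure = DagStructure(names, frozenset(arcs))
        cpts = {}
        for child in names:
            r = schema.variable(child).cardinality
            q = int(np.prod([schema.variable(p).cardinality
                             for p in structure.parents(child)], dtype=int))
            rows = np.vstack([
                rng.dirichlet(np.full(r, config.cpt_concentration))
                for _ in range(q)
            ])
            cpts[child] = Cpt(child, structure.parents(child), rows)
        archetypes.append(BayesianNetwork(schema.variables, structure, cpts))
    return archetypes


def generate_annotations(archetype: BayesianNetwork,
                         config: SyntheticStudyConfig,
                         neuron_id: str = "n0",
                         seed: int | np.random.SeedSequence | None = None
                         ) -> AnnotationMatrix:
    """Simulate one annotator panel for a neuron of the given archetype.

    Each row is the archetype joint with probability 1 - ambiguity, a
    uniform draw over Omega otherwise.  The C4 "no" rule is then enforced
    per row; a translaminar+displaced row that drew "no" is reassigned a
    uniformly random directional category.  A configurable fraction of
    rows is flagged uncharacterized (no class values).
    """
    if seed is None:
        seed = _seq(config, 2)
    rng = np.random.default_rng(seed)
    schema = config.schema
    n = config.annotators_per_neuron
    cards = schema.cardinalities
    arch_codes = logic_sample(archetype, n, seed=rng.integers(2**31)).codes
    unif_codes = np.column_stack([
        rng.integers(0, c, size=n) for c in cards
    ])
    contaminate = rng.random(n) < config.ambiguity
    codes = np.where(contaminate[:, None], unif_codes, arch_codes)
    df = pd.DataFrame({
        v.name: [v.categories[c] for c in codes[:, j]]
        for j, v in enumerate(schema.variables)
    })
    # enforce the C4 "no" rule row by row
    trans_disp = (df["C1"] == "translaminar") & (df["C3"] == "displaced")
    df.loc[~trans_disp, "C4"] = "no"
    bad = trans_disp & (df["C4"] == "no")
    if bad.any():
        df.loc[bad, "C4"] = rng.choice(_C4_DIRECTIONAL, size=int(bad.sum()))
    df.insert(0, "annotator_id", [f"a{i}" for i in range(n)])
    df["characterized"] = True
    n_unchar = int(round(config.uncharacterized_fraction * n))
    if n_unchar:
        drop = rng.choice(n, size=n_unchar, replace=False)
        df.loc[drop, "characterized"] = False
        df.loc[drop, list(schema.names)] = pd.NA
    return AnnotationMatrix(neuron_id, df, annotator_count_total=n, schema=schema)


def generate_neuron_swc(archetype_id: int, config: SyntheticStudyConfig,
                        seed: int | np.random.SeedSequence | None = None,
                        vertical_drift: float | None = None,
                        lateral_spread: float | None = None,
                        n_branches: int = 4, steps_per_branch: int = 40,
                        step_um: float = 12.0) -> Reconstruction:
    """Grow a branching-random-walk axon with archetype-biased geometry.

    Per-archetype biases (vertical drift, lateral spread, length scale)
    are drawn reproducibly from the study seed; explicit ``vertical_drift``
    / ``lateral_spread`` override them for controlled fixtures.  The
    reconstruction is a single-point soma, a short dendrite stub, and the
    axon forest — the minimum the morphometry stage consumes.
    """
    bias_rng = np.random.default_rng(_seq(config, 3, int(archetype_id)))
    drift = bias_rng.uniform(-0.7, 0.7)
    spread = bias_rng.uniform(0.3, 1.2)
    length_scale = bias_rng.uniform(0.7, 1.3)
    if vertical_drift is not None:
        drift = vertical_drift
    if lateral_spread is not None:
        spread = lateral_spread
    rng = np.random.default_rng(_seq(config, 3) if seed is None else seed)

    points = [SwcPoint(1, 1, 0.0, 0.0, 0.0, 5.0, -1)]
    next_id = 2
    # dendrite stub so the tracing is a realistic multi-type forest
    for i, dy in enumerate((8.0, 16.0)):
        points.append(SwcPoint(next_id, 3, 2.0 * (i + 1), dy, 0.0, 1.0,
                               1 if i == 0 else next_id - 1))
        next_id += 1
    steps = max(2, int(round(steps_per_branch * length_scale)))
    for _ in range(n_branches):
        pos = np.zeros(3)
        parent = 1
        for _ in range(steps):
            lateral = spread * rng.standard_normal(2)
            vertical = drift + 0.5 * rng.standard_normal()
            v = np.array([lateral[0], vertical, lateral[1] * 0.5])
            norm = np.linalg.norm(v)
            if norm < 1e-9:
                v = np.array([0.0, 1.0, 0.0])
                norm = 1.0
            pos = pos + step_um * v / norm
            points.append(SwcPoint(next_id, 2, float(pos[0]), float(pos[1]),
                                   float(pos[2]), 0.5, parent))
            parent = next_id
            next_id += 1
    return Reconstruction(tuple(points))


@dataclass
class SyntheticStudy:
    """A coherent in-memory study: every pipeline stage's inputs."""

    config: SyntheticStudyConfig
    archetypes: list[BayesianNetwork]
    archetype_ids: np.ndarray
    matrices: list[AnnotationMatrix]
    lbns: list[BayesianNetwork]
    features: pd.DataFrame
    reconstructions: list[Reconstruction]
    metadata: list[NeuronMetadata]

    @property
    def neuron_ids(self) -> list[str]:
        return list(self.features.index)

    def feature_matrix(self) -> np.ndarray:
        return self.features[list(FEATURE_NAMES)].to_numpy(dtype=float)

    def write(self, out_dir) -> dict[str, Path]:
        """Write the five study artifacts (SWC dir + four tables)."""
        from . import io as _io
        from .morphometry import write_swc

        out = Path(out_dir)
        swc_dir = out / "swc"
        swc_dir.mkdir(parents=True, exist_ok=True)
        for nid, recon in zip(self.neuron_ids, self.reconstructions):
            write_swc(recon, swc_dir / f"{nid}.swc")
        paths = {
            "swc_dir": swc_dir,
            "metadata": out / "metadata.csv",
            "annotations": out / "annotations.csv",
            "features": out / "features.csv",
            "lbns": out / "lbns.json",
        }
        _io.write_metadata(self.metadata, paths["metadata"])
        _io.write_annotations(self.matrices, paths["annotations"])
        _io.write_features(self.features, paths["features"])
        _io.write_lbns(dict(zip(self.neuron_ids, self.lbns)), paths["lbns"])
        return paths


def _cluster_centroids(n_clusters: int, n_features: int, separation: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Randomly rotated regular-simplex vertices with edge = separation
    in units of the within-cluster radial sd (sqrt(m) per-feature sd)."""
    if n_clusters > n_features:
        raise ValueError("need n_archetypes <= number of features")
    edge = separation * np.sqrt(n_features)
    cent = np.zeros((n_clusters, n_features))
    for a in range(n_clusters):
        cent[a, a] = edge / np.sqrt(2.0)
    rot = ortho_group.rvs(n_features, random_state=rng)
    return cent @ rot


def generate_study(config: SyntheticStudyConfig | None = None,
                   learn: bool = True) -> SyntheticStudy:
    """Generate the full synthetic study, reproducibly from the seed."""
    config = config or SyntheticStudyConfig()
    archetypes = generate_archetypes(config)
    n = config.n_neurons
    archetype_ids = np.arange(n) % config.n_archetypes

    matrices = []
    for i in range(n):
        matrices.append(generate_annotations(
            archetypes[archetype_ids[i]], config,
            neuron_id=f"n{i:04d}", seed=_seq(config, 2, i),
        ))
    lbns = [
        learn_lbn(m, score="bde", ess=1.0, seed=config.seed) for m in matrices
    ] if learn else []

    rng_feat = np.random.default_rng(_seq(config, 4))
    centroids = _cluster_centroids(
        config.n_archetypes, len(FEATURE_NAMES), config.feature_separation,
        rng_feat,
    )
    X = centroids[archetype_ids] + rng_feat.standard_normal((n, len(FEATURE_NAMES)))
    features = pd.DataFrame(X, columns=list(FEATURE_NAMES),
                            index=[f"n{i:04d}" for i in range(n)])
    features.index.name = "neuron_id"

    recons = [
        generate_neuron_swc(int(archetype_ids[i]), config, seed=_seq(config, 3, i))
        for i in range(n)
    ]
    metadata = [
        NeuronMetadata(f"n{i:04d}", 200.0, 300.0) for i in range(n)
    ]
    return SyntheticStudy(config, archetypes, archetype_ids, matrices, lbns,
                          features, recons, metadata)
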