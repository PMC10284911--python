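"""Stimulus–response relationship scoring, p-value calibration and binning.

A small feed-forward neural network scores the relationship between a stimulus
protein set (drug targets with action signs) and a response protein set
(condition effectors with expected directions) on a 0–100% scale.  The score is
100 x the classifier's predicted probability that the relationship is real,
learned from the labeled truth table.

Scores are mapped to categories by fixed bins: high (+++) for scores in
[77, 100], medium (++) in [38, 77), low (+) below 38, corresponding to
p < 0.05, p < 0.25 and p > 0.25 respectively.  An empirical permutation
p-value against random same-cardinality protein-set pairs is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .knowledge_base import Effector, ProteinRef, Restriction, TruthTable
from .network_builder import Interactome, ResponseNetwork
from .propagation_model import (
    CompiledNetwork,
    MoAModel,
    compile_network,
    predicted_activity,
    propagate,
    unit_parameters,
)

HIGH_SCORE_MIN = 77.0
MEDIUM_SCORE_MIN = 38.0

CATEGORY_SYMBOLS = {"high": "+++", "medium": "++", "low": "+"}


@dataclass(frozen=True)
class RelationshipFeatures:
    """Fixed-length descriptor of one (stimulus set, response set) pair.

    Distances are shortest-path lengths in the undirected network view;
    unreachable pairs use the sentinel ``diameter + 1``.  All terms are
    invariant to the ordering of proteins within either set.
    """

    mean_abs_activity: float
    sign_agreement: float
    path_sign_agreement: float
    mean_distance: float
    min_distance: float
    n_stimulus: int
    n_response: int
    overlap: int

    def vector(self) -> np.ndarray:
        return np.array(
            [
                self.mean_abs_activity,
                self.sign_agreement,
                self.path_sign_agreement,
                self.mean_distance,
                self.min_distance,
                float(self.n_stimulus),
                float(self.n_response),
                float(self.overlap),
            ]
        )

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vector())):
            raise ValueError("non-finite relationship feature")


@dataclass(frozen=True)
class RelationshipScore:
    score: float           # percent in [0, 100]
    p_value: float | None  # empirical, when a null is available
    category: str          # derived from score via the fixed bins

    def __post_init__(self) -> None:
        if categorize_score(self.score) != self.category:
            raise ValueError("category inconsistent with score bins")


def _distance_sentinel(graph: nx.Graph) -> float:
    """Sentinel for unreachable pairs: diameter of the largest component + 1."""
    if graph.number_of_nodes() == 0:
        return 1.0
    diam = 0
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        ecc = nx.eccentricity(sub)
        diam = max(diam, max(ecc.values()))
    return float(diam + 1)


def featurize_pair(
    stimulus_set: Mapping[str, int],
    response_set: Iterable[Effector],
    network: Interactome | ResponseNetwork | CompiledNetwork,
    moa_ensemble: MoAModel | None = None,
    sentinel: float | None = None,
) -> RelationshipFeatures:
    """Descriptor of how a stimulus set relates to a response set.

    Activities come from the ensemble's mean predicted activity when an MoA
    model is given, otherwise from propagating the stimulus through the
    untrained unit-weight network.  ``sign_agreement`` is the fraction of
    mapped response effectors whose propagated activity sign matches their
    expected direction.
    """
    net = compile_network(network)
    stim = {a: s for a, s in stimulus_set.items() if a in net.node_index}
    resp = [e for e in response_set if e.protein.accession in net.node_index]
    if not stim and not resp:
        raise ValueError("both protein sets are fully unmapped")

    if moa_ensemble is not None:
        acts = predicted_activity(moa_ensemble)
    else:
        acts = propagate(net, unit_parameters(net), stim).activities

    if resp:
        vals = np.array([acts.get(e.protein.accession, 0.0) for e in resp])
        dirs = np.array([e.direction for e in resp], dtype=float)
        mean_abs = float(np.mean(np.abs(vals)))
        agreement = float(np.mean((np.sign(vals) == dirs) & (np.abs(vals) > 0)))
    else:
        mean_abs, agreement = 0.0, 0.0

    graph = net.graph
    if sentinel is None:
        sentinel = _distance_sentinel(graph)
    resp_accs = {e.protein.accession for e in resp}
    paths_by_stim = {
        s: nx.single_source_shortest_path(graph, s) for s in sorted(stim)
    }
    dists = []
    for s in sorted(stim):
        paths = paths_by_stim[s]
        for t in sorted(resp_accs):
            dists.append(float(len(paths[t]) - 1) if t in paths else sentinel)
    mean_d = float(np.mean(dists)) if dists else sentinel
    min_d = float(np.min(dists)) if dists else sentinel

    # parity of the shortest mechanism path: does the sign product along the
    # nearest target -> effector path reproduce the expected direction?
    path_agree = []
    for eff in resp:
        t = eff.protein.accession
        best_path: list[str] | None = None
        for s in sorted(stim):
            p = paths_by_stim[s].get(t)
            if p is not None and (best_path is None or len(p) < len(best_path)):
                best_path = p
        if best_path is None:
            path_agree.append(0.0)
            continue
        parity = stim[best_path[0]]
        for u, v in zip(best_path, best_path[1:]):
            parity *= graph[u][v].get("sign", 1)
        path_agree.append(1.0 if parity == eff.direction else 0.0)
    path_sign = float(np.mean(path_agree)) if path_agree else 0.0

    return RelationshipFeatures(
        mean_abs_activity=mean_abs,
        sign_agreement=agreement,
        path_sign_agreement=path_sign,
        mean_distance=mean_d,
        min_distance=min_d,
        n_stimulus=len(stim),
        n_response=len(resp),
        overlap=len(set(stim) & resp_accs),
    )


def restriction_features(
    restriction: Restriction,
    network: Interactome | ResponseNetwork | CompiledNetwork,
    moa_ensemble: MoAModel | None = None,
    sentinel: float | None = None,
) -> RelationshipFeatures:
    """Features of one truth-table restriction, with directions adjusted for
    the relation ("treats" expects effectors driven opposite to pathology)."""
    response = [
        Effector(e.protein, restriction.expected_direction(e))
        for e in sorted(restriction.response)
    ]
    return featurize_pair(
        restriction.stimulus.stimulus(), response, network, moa_ensemble, sentinel
    )


def build_classifier(seed: int = 0) -> Pipeline:
    """Deliberately small network: one hidden layer of 16 units, L2-regularized
    and fit with lbfgs, so training on desk-scale truth tables takes seconds.

    Truth tables at this scale hold a few dozen examples; a held-out early
    stopping fold would be noise-dominated, so capacity control is by the L2
    penalty instead.
    """
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPClassifier(
                    hidden_layer_sizes=(16,),
                    solver="lbfgs",
                    alpha=1.0,
                    max_iter=3000,
                    random_state=seed,
                ),
            ),
        ]
    )


def train_classifier(
    truth_table: TruthTable,
    network: Interactome | ResponseNetwork | CompiledNetwork,
    k_folds: int = 5,
    seed: int = 0,
    moa_ensembles: Mapping[str, MoAModel] | None = None,
) -> tuple[Pipeline, float]:
    """Train the relationship classifier and report stratified k-fold CV accuracy.

    Each truth-table restriction becomes one example; optional per-drug MoA
    ensembles supply trained activities (untrained unit-weight propagation is
    used otherwise).  Returns the classifier refit on all examples together
    with the mean cross-validation accuracy.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    labels = {r.label for r in truth_table.restrictions}
    if labels != {True, False}:
        raise ValueError("truth table must contain both labels")

    net = compile_network(network)
    sentinel = _distance_sentinel(net.graph)
    X, y = [], []
    for r in truth_table.restrictions:
        moa = (moa_ensembles or {}).get(r.stimulus.name)
        X.append(restriction_features(r, net, moa, sentinel).vector())
        y.append(int(r.label))
    X = np.vstack(X)
    y = np.array(y)

    clf = build_classifier(seed)
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(clf, X, y, cv=cv, scoring="accuracy")
    clf.fit(X, y)
    return clf, float(np.mean(scores))


def score_pair(classifier: Pipeline, features: RelationshipFeatures) -> float:
    """Relationship score: 100 x predicted probability of a true relationship."""
    proba = classifier.predict_proba(features.vector()[None, :])[0]
    true_col = list(classifier.classes_).index(1)
    return float(100.0 * proba[true_col])


def calibrate_pvalue(score: float, null_scores: Sequence[float]) -> float:
    """Empirical add-one p-value of a score against a permutation null.

    p = (1 + #{null >= score}) / (1 + N); ties count toward the null, and the
    add-one form keeps p > 0.  Monotone non-increasing in the score.
    """
    if len(null_scores) == 0:
        raise ValueError("empty null distribution")
    null = np.asarray(null_scores, dtype=float)
    return float((1 + int(np.sum(null >= score))) / (1 + null.size))


def null_scores(
    classifier: Pipeline,
    network: Interactome | ResponseNetwork | CompiledNetwork,
    n_stimulus: int,
    n_response: int,
    n_null: int = 99,
    seed: int = 0,
) -> list[float]:
    """Scores of random protein-set pairs of matched cardinalities."""
    net = compile_network(network)
    rng = np.random.default_rng(seed)
    sentinel = _distance_sentinel(net.graph)
    out = []
    nodes = np.array(net.nodes)
    for _ in range(n_null):
        stim_nodes = rng.choice(nodes, size=min(n_stimulus, len(nodes)), replace=False)
        resp_nodes = rng.choice(nodes, size=min(n_response, len(nodes)), replace=False)
        stim = {str(a): int(rng.choice([-1, 1])) for a in stim_nodes}
        resp = [
            Effector(ProteinRef(str(a)), int(rng.choice([-1, 1]))) for a in resp_nodes
        ]
        out.append(score_pair(classifier, featurize_pair(stim, resp, net, None, sentinel)))
    return out


def categorize_score(score: float) -> str:
    """Fixed category bins: [77, 100] high, [38, 77) medium, [0, 38) low."""
    if not (0.0 <= score <= 100.0):
        raise ValueError(f"score {score} outside [0, 100]")
    if score >= HIGH_SCORE_MIN:
        return "high"
    if score >= MEDIUM_SCORE_MIN:
        return "medium"
    return "low"


def relationship_score(
    score: float, null: Sequence[float] | None = None
) -> RelationshipScore:
    return RelationshipScore(
        score=score,
        p_value=calibrate_pvalue(score, null) if null is not None else None,
        category=categorize_score(score),
    )
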