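"""Synthetic questionnaire data from a planted Gaussian graphical model.

Because no participant-level data are distributed with the study this
package emulates, every downstream stage (network estimation, bootstrap,
pathways) is exercised on data generated from a *known* sparse
partial-correlation structure.  Generation is latent-Gaussian-then-round:
draw multivariate normal scores whose partial correlations equal the
planted graph, rescale to the questionnaire means/SDs, round to integers
and clip to the scale bounds.  Subscale sums are quasi-continuous, so this
captures the features that matter for correlation-based network
estimation without simulating individual items.

:func:`paper_topology_spec` returns ready-made specifications for the two
clinical groups (bulimia nervosa, n=181; binge eating disorder, n=144)
whose planted graphs route every maltreatment node through emotional
abuse and then through group-specific symptom bridges (ineffectiveness in
BN, impulsivity in BED) toward the ED-specific symptoms body
dissatisfaction and bulimia, with marginal means/SDs matching the
published group descriptives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ALL_NODES, CM_NODES, ED_NODES, SubscaleDataset, default_roles


class InfeasibleStructureError(ValueError):
    """The requested partial-correlation matrix has no valid Gaussian model."""


class SpecError(ValueError):
    """Structurally invalid synthetic specification."""


# ---------------------------------------------------------------------------
# score-scale conventions
# ---------------------------------------------------------------------------

#: Nominal EDI-2 item counts per subscale. The instrument's published item
#: counts; scores are treated as 0-3 per item, so bounds default to
#: [0, 3 * items]. These are configuration, not fact: studies differ in
#: scoring (0-3 vs recoded 1-6), so bounds are permissive and overridable.
EDI2_NOMINAL_ITEMS: dict[str, int] = {
    "ineffectiveness": 10,
    "social_insecurity": 8,
    "drive_for_thinness": 7,
    "interoceptive_awareness": 10,
    "maturity_fear": 8,
    "body_dissatisfaction": 9,
    "perfectionism": 6,
    "interpersonal_distrust": 7,
    "impulsivity": 11,
    "bulimia": 7,
    "asceticism": 8,
}

#: CTQ subscales: 5 items each, 1-5 per item (CTQ-SF scoring), so sum
#: scores live in [5, 25].
CTQ_BOUNDS: tuple[int, int] = (5, 25)


def default_score_bounds(names: list[str] | tuple[str, ...]) -> np.ndarray:
    """Per-variable [min, max] integer bounds under the default scoring."""
    bounds = []
    for n in names:
        if n in CM_NODES:
            bounds.append(CTQ_BOUNDS)
        elif n in EDI2_NOMINAL_ITEMS:
            bounds.append((0, 3 * EDI2_NOMINAL_ITEMS[n]))
        else:  # unknown variable: effectively unbounded integer scale
            bounds.append((-(10**9), 10**9))
    return np.asarray(bounds, dtype=float)


# Published group descriptives (mean, SD) used as marginal targets.
GROUP_MARGINALS: dict[str, dict[str, tuple[float, float]]] = {
    "BN": {
        "ineffectiveness": (12.85, 7.89),
        "maturity_fear": (8.75, 5.72),
        "social_insecurity": (7.71, 4.30),
        "body_dissatisfaction": (16.02, 7.25),
        "perfectionism": (7.23, 4.60),
        "interpersonal_distrust": (6.77, 4.81),
        "impulsivity": (9.86, 7.22),
        "drive_for_thinness": (15.55, 5.27),
        "bulimia": (10.58, 5.64),
        "interoceptive_awareness": (14.02, 6.89),
        "asceticism": (9.23, 4.46),
        "emotional_neglect": (13.30, 4.83),
        "emotional_abuse": (10.21, 4.71),
        "sexual_abuse": (6.69, 3.61),
        "physical_neglect": (7.28, 2.51),
        "physical_abuse": (6.89, 3.08),
    },
    "BED": {
        "ineffectiveness": (9.58, 7.32),
        "maturity_fear": (6.68, 5.02),
        "social_insecurity": (5.24, 3.31),
        "body_dissatisfaction": (18.88, 6.13),
        "perfectionism": (6.03, 4.43),
        "interpersonal_distrust": (4.97, 4.33),
        "impulsivity": (5.43, 5.17),
        "drive_for_thinness": (12.81, 5.63),
        "bulimia": (8.13, 5.18),
        "interoceptive_awareness": (8.54, 6.12),
        "asceticism": (6.61, 3.68),
        "emotional_neglect": (11.76, 4.90),
        "emotional_abuse": (9.96, 4.47),
        "sexual_abuse": (6.55, 3.34),
        "physical_neglect": (6.97, 2.21),
        "physical_abuse": (6.25, 2.51),
    },
}

GROUP_SIZES: dict[str, int] = {"BN": 181, "BED": 144}


# ---------------------------------------------------------------------------
# spec
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpec:
    """Ground-truth generating model for one synthetic sample.

    ``true_partial_corr`` is the planted partial-correlation matrix
    (symmetric, unit diagonal, off-diagonals in (-1, 1)); the implied
    precision matrix (unit conditional variances) must be positive
    definite.  ``means``/``sds`` set the questionnaire-scale marginals,
    ``score_bounds`` the per-variable integer clipping range.
    """

    node_names: list[str]
    true_partial_corr: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    score_bounds: np.ndarray
    n_subjects: int
    group_label: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_partial_corr = np.asarray(self.true_partial_corr, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.score_bounds = np.asarray(self.score_bounds, dtype=float)
        self.validate()

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def validate(self) -> None:
        p = self.n_nodes
        P = self.true_partial_corr
        if P.shape != (p, p):
            raise SpecError(f"partial-correlation matrix must be {p}x{p}, got {P.shape}")
        if not np.allclose(P, P.T, atol=1e-12):
            raise SpecError("partial-correlation matrix must be symmetric")
        if not np.allclose(np.diag(P), 1.0, atol=1e-12):
            raise SpecError("partial-correlation matrix must have unit diagonal")
        off = P[~np.eye(p, dtype=bool)]
        if off.size and np.max(np.abs(off)) >= 1.0:
            raise SpecError("off-diagonal partial correlations must lie in (-1, 1)")
        for arr, name in ((self.means, "means"), (self.sds, "sds")):
            if arr.shape != (p,):
                raise SpecError(f"{name} must have length {p}")
        if np.any(self.sds <= 0):
            raise SpecError("sds must be positive")
        if self.score_bounds.shape != (p, 2):
            raise SpecError(f"score_bounds must be {p}x2")
        if np.any(self.score_bounds[:, 0] >= self.score_bounds[:, 1]):
            raise SpecError("score_bounds min must be < max for every variable")
        if self.n_subjects < 1:
            raise SpecError("n_subjects must be positive")
        # feasibility: implied precision must be PD (raises if not)
        pcor_to_precision(P, np.ones(p))

    # -- serialization (row-major matrix, plain JSON types) -----------------

    def to_json(self) -> str:
        payload = {
            "node_names": list(self.node_names),
            "true_partial_corr": self.true_partial_corr.ravel().tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "score_bounds": self.score_bounds.tolist(),
            "n_subjects": int(self.n_subjects),
            "group_label": self.group_label,
            "seed": int(self.seed),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        d = json.loads(text)
        p = len(d["node_names"])
        return cls(
            node_names=d["node_names"],
            true_partial_corr=np.asarray(d["true_partial_corr"], dtype=float).reshape(p, p),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            score_bounds=np.asarray(d["score_bounds"], dtype=float),
            n_subjects=int(d["n_subjects"]),
            group_label=d.get("group_label", ""),
            seed=int(d.get("seed", 0)),
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def pcor_to_precision(P: np.ndarray, diag_scale: np.ndarray) -> np.ndarray:
    """Build a precision matrix realizing the partial correlations ``P``.

    K_ii = diag_scale_i and K_ij = -P_ij * sqrt(K_ii * K_jj) for i != j.
    Any positive ``diag_scale`` yields the same partial correlations; unit
    conditional variances (all ones) are the canonical representative.

    Raises
    ------
    InfeasibleStructureError
        If the resulting matrix is not positive definite, i.e. no Gaussian
        distribution has these partial correlations.
    """
    P = np.asarray(P, dtype=float)
    diag_scale = np.asarray(diag_scale, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise SpecError("P must be square")
    if not np.allclose(P, P.T, atol=1e-12):
        raise SpecError("P must be symmetric")
    if not np.allclose(np.diag(P), 1.0, atol=1e-12):
        raise SpecError("P must have unit diagonal")
    if np.any(diag_scale <= 0):
        raise SpecError("diag_scale must be positive")
    root = np.sqrt(diag_scale)
    K = -P * np.outer(root, root)
    np.fill_diagonal(K, diag_scale)
    K = (K + K.T) / 2.0
    eigmin = float(np.linalg.eigvalsh(K)[0])
    if eigmin <= 1e-12:
        raise InfeasibleStructureError(
            "infeasible partial correlation structure: implied precision has "
            f"minimum eigenvalue {eigmin:.3e}"
        )
    return K


def implied_correlation(P: np.ndarray) -> np.ndarray:
    """Marginal correlation matrix implied by partial correlations ``P``."""
    K = pcor_to_precision(P, np.ones(P.shape[0]))
    cov = np.linalg.inv(K)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return (corr + corr.T) / 2.0


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round halves away from zero (numpy's default rounds to even)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def generate_dataset(spec: SyntheticSpec) -> SubscaleDataset:
    """Draw one integer score table from the planted model.

    Latent scores are multivariate normal with unit marginal variances and
    the correlation structure implied by ``spec.true_partial_corr``; they
    are then scaled by ``sds``, shifted by ``means``, rounded
    half-away-from-zero and clipped to ``score_bounds``.  Output is a pure
    function of the spec (including its seed).
    """
    if spec.n_subjects < 2:
        raise SpecError("degenerate sample: n_subjects must be at least 2")
    corr = implied_correlation(spec.true_partial_corr)
    rng = np.random.default_rng(spec.seed)
    latent = rng.multivariate_normal(
        np.zeros(spec.n_nodes), corr, size=spec.n_subjects, method="cholesky"
    )
    raw = latent * spec.sds + spec.means
    scores = _round_half_away(raw)
    scores = np.clip(scores, spec.score_bounds[:, 0], spec.score_bounds[:, 1])
    frame = pd.DataFrame(scores.astype(np.int64), columns=list(spec.node_names))
    return SubscaleDataset(
        scores=frame,
        variable_role=default_roles(spec.node_names),
        group_label=spec.group_label,
        provenance=f"synthetic(seed={spec.seed})",
    )


# ---------------------------------------------------------------------------
# planted topologies
# ---------------------------------------------------------------------------

# Planted edge weights (partial correlations). Maltreatment converges on
# emotional abuse; the bridge into the symptom network differs by group.
_BN_EDGES: tuple[tuple[str, str, float], ...] = (
    ("emotional_neglect", "emotional_abuse", 0.25),
    ("sexual_abuse", "emotional_abuse", 0.25),
    ("physical_neglect", "emotional_abuse", 0.25),
    ("physical_abuse", "emotional_abuse", 0.25),
    ("emotional_abuse", "ineffectiveness", 0.30),
    ("ineffectiveness", "body_dissatisfaction", 0.35),
    ("ineffectiveness", "interoceptive_awareness", 0.30),
    ("interoceptive_awareness", "bulimia", 0.35),
)

_BED_EDGES: tuple[tuple[str, str, float], ...] = (
    ("emotional_neglect", "emotional_abuse", 0.25),
    ("sexual_abuse", "emotional_abuse", 0.25),
    ("physical_neglect", "emotional_abuse", 0.25),
    ("physical_abuse", "emotional_abuse", 0.25),
    ("emotional_abuse", "impulsivity", 0.30),
    ("impulsivity", "ineffectiveness", 0.30),
    ("ineffectiveness", "body_dissatisfaction", 0.35),
    ("impulsivity", "interoceptive_awareness", 0.30),
    ("interoceptive_awareness", "bulimia", 0.35),
)

#: weight of filler edges among symptom nodes off the planted pathways
_BACKGROUND_WEIGHT = 0.15
#: fixed stream for drawing which background pairs get an edge
_BACKGROUND_SEED = 20210328


def _planted_matrix(
    edges: tuple[tuple[str, str, float], ...],
    n_background: int,
) -> np.ndarray:
    names = list(ALL_NODES)
    idx = {n: i for i, n in enumerate(names)}
    P = np.eye(len(names))
    for a, b, w in edges:
        P[idx[a], idx[b]] = P[idx[b], idx[a]] = w
    # background edges only among ED nodes not on a planted pathway, so the
    # planted shortest routes stay shortest
    on_path = {a for a, _, _ in edges} | {b for _, b, _ in edges}
    free = [n for n in ED_NODES if n not in on_path]
    pairs = [(a, b) for i, a in enumerate(free) for b in free[i + 1 :]]
    rng = np.random.default_rng(_BACKGROUND_SEED)
    chosen = rng.choice(len(pairs), size=min(n_background, len(pairs)), replace=False)
    for k in sorted(chosen):
        a, b = pairs[k]
        P[idx[a], idx[b]] = P[idx[b], idx[a]] = _BACKGROUND_WEIGHT
    return P


def paper_topology_spec(
    group: str,
    n_subjects: int | None = None,
    seed: int = 0,
    n_background: int = 6,
) -> SyntheticSpec:
    """Ready-made 16-node generating model for one clinical group.

    ``group`` must be ``"BN"`` (bulimia nervosa) or ``"BED"`` (binge
    eating disorder).  The planted graph contains, in both groups, edges
    from every maltreatment node to emotional abuse; in BN the chain
    emotional abuse - ineffectiveness - body dissatisfaction with
    ineffectiveness - interoceptive awareness - bulimia; in BED emotional
    abuse - impulsivity, impulsivity - ineffectiveness - body
    dissatisfaction and impulsivity - interoceptive awareness - bulimia.
    ``n_background`` filler edges (|w| = 0.15) are planted among the
    remaining symptom nodes.  Sample sizes default to the study groups
    (181 BN, 144 BED); marginal means/SDs default to the published group
    descriptives.
    """
    if group not in GROUP_MARGINALS:
        raise SpecError(
            f"unknown group {group!r}; valid labels: {sorted(GROUP_MARGINALS)}"
        )
    edges = _BN_EDGES if group == "BN" else _BED_EDGES
    P = _planted_matrix(edges, n_background)
    marg = GROUP_MARGINALS[group]
    means = np.array([marg[n][0] for n in ALL_NODES])
    sds = np.array([marg[n][1] for n in ALL_NODES])
    return SyntheticSpec(
        node_names=list(ALL_NODES),
        true_partial_corr=P,
        means=means,
        sds=sds,
        score_bounds=default_score_bounds(ALL_NODES),
        n_subjects=n_subjects if n_subjects is not None else GROUP_SIZES[group],
        group_label=group,
        seed=seed,
    )


def random_sparse_spec(
    n_nodes: int,
    n_edges: int,
    seed: int,
    weight_range: tuple[float, float] = (0.25, 0.35),
    n_subjects: int = 500,
    max_tries: int = 200,
) -> SyntheticSpec:
    """Random sparse feasible truth for simulation studies.

    Draws ``n_edges`` distinct node pairs uniformly and assigns each a
    weight uniform in ``weight_range`` with random sign, re-drawing until
    the implied precision is positive definite.  Marginals are benign
    (mean 50, SD 10, wide bounds) so integer rounding is negligible
    relative to the scale.
    """
    rng = np.random.default_rng(seed)
    names = [f"v{i:02d}" for i in range(n_nodes)]
    pairs = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    if n_edges > len(pairs):
        raise SpecError("more edges requested than node pairs")
    for _ in range(max_tries):
        P = np.eye(n_nodes)
        for k in rng.choice(len(pairs), size=n_edges, replace=False):
            i, j = pairs[k]
            w = rng.uniform(*weight_range) * rng.choice([-1.0, 1.0])
            P[i, j] = P[j, i] = w
        try:
            pcor_to_precision(P, np.ones(n_nodes))
        except InfeasibleStructureError:
            continue
        return SyntheticSpec(
            node_names=names,
            true_partial_corr=P,
            means=np.full(n_nodes, 50.0),
            sds=np.full(n_nodes, 10.0),
            score_bounds=np.tile([-1000.0, 1000.0], (n_nodes, 1)),
            n_subjects=n_subjects,
            group_label="sim",
            seed=int(rng.integers(2**31 - 1)),
        )
    raise InfeasibleStructureError(
        f"no feasible random structure found in {max_tries} tries"
    )
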