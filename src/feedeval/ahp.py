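"""Analytic hierarchy process: Saaty-scale judgment matrices, eigenvector
priorities, consistency checking and hierarchical group synthesis.

Experts compare items pairwise on the 1-9 scale (with intermediates and
reciprocals); each reciprocal matrix yields a priority vector — the
normalized principal right eigenvector, computed here by deterministic power
iteration — and a consistency report: CI = (lambda_max - n)/(n - 1) and
CR = CI / RI with Saaty's random-index table.  CR < 0.1 marks a matrix
acceptably consistent.  Experts are aggregated by arithmetic averaging of
priority vectors (a geometric mean of matrix elements is offered as an
alternative), and the hierarchy is synthesised as
global(alt) = sum_c w(c) * w(alt | c).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

#: Saaty's random consistency index, indexed by matrix order n (1-based).
RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
                6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}

SCALE_MIN, SCALE_MAX = 1.0 / 9.0, 9.0


class MatrixValidationError(ValueError):
    """Raised for non-reciprocal or out-of-scale judgment matrices."""


class InconsistentMatrixError(ValueError):
    """Raised when synthesis meets a matrix with CR >= 0.1 and no override."""


@dataclass(frozen=True)
class ConsistencyReport:
    lambda_max: float
    CI: float
    RI: float
    CR: float
    acceptable: bool  # CR < 0.1

    @classmethod
    def from_lambda(cls, lambda_max: float, n: int, threshold: float = 0.1):
        ci = max(0.0, (lambda_max - n) / (n - 1)) if n > 2 else 0.0
        ri = RANDOM_INDEX.get(n, 1.49)
        cr = ci / ri if ri > 0 else 0.0
        return cls(lambda_max=lambda_max, CI=ci, RI=ri, CR=cr,
                   acceptable=bool(cr < threshold))


@dataclass
class PairwiseMatrix:
    """Reciprocal judgment matrix over ordered item labels."""

    items: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.items = tuple(self.items)
        A = np.asarray(self.values, dtype=float)
        n = len(self.items)
        if A.shape != (n, n):
            raise MatrixValidationError(f"matrix shape {A.shape} != ({n},{n})")
        if not 2 <= n <= 10:
            raise MatrixValidationError("supported matrix order is 2..10")
        if not np.allclose(np.diag(A), 1.0):
            raise MatrixValidationError("diagonal must be 1")
        if np.any(A < SCALE_MIN - 1e-9) or np.any(A > SCALE_MAX + 1e-9):
            raise MatrixValidationError("entries must lie in [1/9, 9]")
        if not np.allclose(A * A.T, 1.0, rtol=1e-6):
            raise MatrixValidationError("matrix is not reciprocal (a_jk * a_kj != 1)")
        self.values = A

    @property
    def n(self) -> int:
        return len(self.items)

    @classmethod
    def from_upper_triangle(cls, items: Sequence[str], upper: Mapping[tuple[str, str], float]):
        """Build a full matrix from upper-triangle judgments; reciprocals filled."""
        items = tuple(items)
        idx = {it: i for i, it in enumerate(items)}
        A = np.eye(len(items))
        for (j, k), v in upper.items():
            A[idx[j], idx[k]] = v
            A[idx[k], idx[j]] = 1.0 / v
        return cls(items, A)


@dataclass(frozen=True)
class PriorityVector:
    """Non-negative item weights summing to one."""

    items: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "items", tuple(self.items))

    def __getitem__(self, item: str) -> float:
        return float(self.weights[self.items.index(item)])

    def as_dict(self) -> dict[str, float]:
        return {it: float(w) for it, w in zip(self.items, self.weights)}


def priorities(
    matrix: PairwiseMatrix, tol: float = 1e-12, max_iter: int = 10_000
) -> tuple[PriorityVector, ConsistencyReport]:
    """Principal eigenvector by power iteration from a uniform start.

    The fixed start and tolerance make results deterministic.  lambda_max is
    the Rayleigh-style mean of (A w) / w at convergence.
    """
    A = matrix.values
    n = matrix.n
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = A @ w
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - w)) < tol:
            w = nxt
            break
        w = nxt
    lam = float(np.mean((A @ w) / w))
    vec = PriorityVector(matrix.items, w / w.sum())
    return vec, ConsistencyReport.from_lambda(lam, n)


def aggregate_experts(
    vectors: Sequence[PriorityVector],
    expert_weights: Sequence[float] | None = None,
) -> PriorityVector:
    """Arithmetic mean of priority vectors over identical item sets."""
    if not vectors:
        raise ValueError("no vectors to aggregate")
    items = vectors[0].items
    for v in vectors[1:]:
        if v.items != items:
            raise ValueError(f"mismatched item sets: {v.items} vs {items}")
    if expert_weights is None:
        ew = np.full(len(vectors), 1.0 / len(vectors))
    else:
        ew = np.asarray(expert_weights, dtype=float)
        if ew.size != len(vectors) or np.any(ew < 0) or ew.sum() == 0:
            raise ValueError("invalid expert weights")
        ew = ew / ew.sum()
    mean = sum(w * v.weights for w, v in zip(ew, vectors))
    return PriorityVector(items, mean / mean.sum())


def geometric_matrix_mean(matrices: Sequence[PairwiseMatrix]) -> PairwiseMatrix:
    """Element-wise geometric mean of judgment matrices (preserves reciprocity)."""
    items = matrices[0].items
    for m in matrices[1:]:
        if m.items != items:
            raise ValueError("mismatched item sets")
    logs = np.mean([np.log(m.values) for m in matrices], axis=0)
    return PairwiseMatrix(items, np.exp(logs))


@dataclass
class ExpertJudgments:
    """One expert's full matrix set: criteria plus per-criterion alternatives."""

    criteria_matrix: PairwiseMatrix
    alternative_matrices: dict[str, PairwiseMatrix]


@dataclass
class AHPModel:
    """Goal / criteria / alternatives hierarchy with per-expert judgments."""

    goal: str
    criteria: tuple[str, ...]
    alternatives: tuple[str, ...]
    experts: list[ExpertJudgments] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.criteria = tuple(self.criteria)
        self.alternatives = tuple(self.alternatives)
        for e, judg in enumerate(self.experts):
            if judg.criteria_matrix.items != self.criteria:
                raise ValueError(f"expert {e}: criteria matrix items mismatch")
            for c in self.criteria:
                if c not in judg.alternative_matrices:
                    raise ValueError(f"expert {e}: missing alternative matrix for {c!r}")
                if judg.alternative_matrices[c].items != self.alternatives:
                    raise ValueError(f"expert {e}: alternative items mismatch for {c!r}")


@dataclass
class SynthesisReport:
    global_weights: PriorityVector
    criteria_weights: PriorityVector
    local_weights: dict[str, PriorityVector]  # criterion -> alternatives
    consistency: list[dict[str, ConsistencyReport]]  # per expert, per matrix
    aggregation: str


def synthesize(
    model: AHPModel,
    aggregation: str = "vector-mean",
    override_consistency: bool = False,
    expert_weights: Sequence[float] | None = None,
) -> SynthesisReport:
    """Hierarchical synthesis of the group model.

    Every matrix must pass CR < 0.1 unless ``override_consistency`` is set.
    ``aggregation='vector-mean'`` averages per-expert priority vectors;
    ``'matrix-geomean'`` takes the element-wise geometric mean of the expert
    matrices first and derives priorities from the pooled matrices.
    """
    if not model.experts:
        raise ValueError("model has no expert judgments")
    consistency: list[dict[str, ConsistencyReport]] = []
    failures: list[str] = []
    per_expert_crit: list[PriorityVector] = []
    per_expert_local: list[dict[str, PriorityVector]] = []
    for e, judg in enumerate(model.experts):
        reports: dict[str, ConsistencyReport] = {}
        vec, rep = priorities(judg.criteria_matrix)
        reports["criteria"] = rep
        if not rep.acceptable:
            failures.append(f"expert {e}: criteria matrix CR={rep.CR:.4f}")
        locs: dict[str, PriorityVector] = {}
        for c in model.criteria:
            lv, lr = priorities(judg.alternative_matrices[c])
            reports[c] = lr
            locs[c] = lv
            if not lr.acceptable:
                failures.append(f"expert {e}: matrix for {c!r} CR={lr.CR:.4f}")
        consistency.append(reports)
        per_expert_crit.append(vec)
        per_expert_local.append(locs)
    if failures and not override_consistency:
        raise InconsistentMatrixError(
            "inconsistent judgment matrices (CR >= 0.1): " + "; ".join(failures)
        )

    if aggregation == "vector-mean":
        crit_w = aggregate_experts(per_expert_crit, expert_weights)
        local = {
            c: aggregate_experts([loc[c] for loc in per_expert_local], expert_weights)
            for c in model.criteria
        }
    elif aggregation == "matrix-geomean":
        crit_w, _ = priorities(
            geometric_matrix_mean([e.criteria_matrix for e in model.experts])
        )
        local = {
            c: priorities(
                geometric_matrix_mean([e.alternative_matrices[c] for e in model.experts])
            )[0]
            for c in model.criteria
        }
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")

    glob = np.zeros(len(model.alternatives))
    for c in model.criteria:
        glob += crit_w[c] * local[c].weights
    return SynthesisReport(
        global_weights=PriorityVector(model.alternatives, glob / glob.sum()),
        criteria_weights=crit_w,
        local_weights=local,
        consistency=consistency,
        aggregation=aggregation,
    )


def consistent_matrix(weights: PriorityVector) -> PairwiseMatrix:
    """The fully consistent matrix a_jk = w_j / w_k implied by given weights."""
    w = weights.weights
    A = np.clip(w[:, None] / w[None, :], SCALE_MIN, SCALE_MAX)
    # re-impose exact reciprocity after clipping
    iu = np.triu_indices(len(w), 1)
    A[(iu[1], iu[0])] = 1.0 / A[iu]
    return PairwiseMatrix(weights.items, A)


# ---------------------------------------------------------------------------
# Model file I/O (YAML/JSON): goal, criteria, alternatives, per-expert matrices


def load_model(path: str | Path) -> AHPModel:
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        raw = yaml.safe_load(path.read_text())
    else:
        raw = json.loads(path.read_text())
    criteria = tuple(raw["criteria"])
    alternatives = tuple(raw["alternatives"])
    experts = []
    for ej in raw["experts"]:
        crit = PairwiseMatrix(criteria, np.asarray(ej["criteria_matrix"], dtype=float))
        alts = {
            c: PairwiseMatrix(alternatives, np.asarray(m, dtype=float))
            for c, m in ej["alternative_matrices"].items()
        }
        experts.append(ExpertJudgments(crit, alts))
    return AHPModel(goal=raw.get("goal", ""), criteria=criteria,
                    alternatives=alternatives, experts=experts)


def dump_model(model: AHPModel, path: str | Path) -> None:
    raw = {
        "goal": model.goal,
        "criteria": list(model.criteria),
        "alternatives": list(model.alternatives),
        "experts": [
            {
                "criteria_matrix": e.criteria_matrix.values.tolist(),
                "alternative_matrices": {
                    c: m.values.tolist() for c, m in e.alternative_matrices.items()
                },
            }
            for e in model.experts
        ],
    }
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        path.write_text(yaml.safe_dump(raw, sort_keys=False))
    else:
        path.write_text(json.dumps(raw, indent=2))
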