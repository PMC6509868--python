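"""The multiple-instance SVM core: bag scoring and the iterative trainers.

The learning problem is the witness-based soft-margin program

    min_s min_{w,b,eps}  1/2 ||w||^2 + C * sum_I eps_I

subject to, for every negative bag, ``-(w^T x_i + b) >= 1 - eps_I`` for each
of its instances (one shared slack per bag), and for every positive bag
``w^T x_{s(I)} + b >= 1 - eps_I`` where ``s(I)`` indexes the bag's
*witness* — the single instance chosen to represent it. A bag is scored by
the maximum instance decision value ``f(x) = sum_k alpha_k K(sv_k, x) + b``
and classified by its sign, so a bag is called bound iff at least one of
its windows looks like a binding site.

The outer minimisation over witness assignments is NP-hard; two iterative
heuristics alternate (a) fitting a standard soft-margin SVM on the current
witnesses plus every negative-bag instance and (b) re-selecting each
positive bag's witness as its highest-scoring instance:

* ``fit_mi_svm`` stops only at an exact fixed point of the witness
  assignment (or at ``max_iter``), the classical MI-SVM loop.
* ``fit_md_svm`` uses a relaxed, stabilised criterion: stop when the
  fraction of changed witnesses drops to ``witness_change_tol``, when the
  relative objective change drops to ``objective_rel_tol``, or when the
  assignment revisits a previous state (a cycle), in which case the
  best-objective state seen is returned. With both tolerances at zero and
  no cycle it reduces exactly to the MI-SVM criterion, but it always
  terminates in a stable state even when the fixed-point iteration
  oscillates.

``brute_force_mil_fit`` solves the outer minimisation exactly by
enumerating every witness assignment; it is practical only for tiny inputs
and serves as an independent optimum to compare the heuristics against.
"""

from __future__ import annotations

import itertools
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import linear_kernel, rbf_kernel
from sklearn.svm import SVC

from .bags import BagConfig, LabeledBag, encode_bag

MODEL_FORMAT = "mdsvm-model"
MODEL_VERSION = 1


class ModelFormatError(ValueError):
    """Raised when a model file is malformed or from another version."""


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of the MIL trainers.

    ``C`` is the soft-margin weight; ``kernel`` is ``"gaussian"`` or
    ``"linear"``; ``gamma`` is the gaussian width (``None`` means the
    scale-aware default ``1 / (4 c)``, the inverse feature dimension).
    ``witness_change_tol`` and ``objective_rel_tol`` parameterise the
    relaxed stopping criterion and are ignored by ``fit_mi_svm``.
    """

    C: float = 1.0
    kernel: str = "gaussian"
    gamma: float | None = None
    max_iter: int = 50
    witness_change_tol: float = 0.01
    objective_rel_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.kernel not in ("gaussian", "linear"):
            raise ValueError(f"unknown kernel: {self.kernel!r}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 <= self.witness_change_tol <= 1.0:
            raise ValueError("witness_change_tol must be in [0, 1]")
        if self.objective_rel_tol < 0:
            raise ValueError("objective_rel_tol must be >= 0")

    def resolve_gamma(self, dim: int) -> float:
        return self.gamma if self.gamma is not None else 1.0 / dim


@dataclass
class MilSvmModel:
    """A trained kernelised decision function plus its witness assignment."""

    support_vectors: np.ndarray  # (n_sv, 4c)
    dual_coef: np.ndarray  # signed y_i * alpha_i, one per support vector
    bias: float
    kernel: str
    gamma: float
    C: float
    window: int
    witnesses: dict[str, int] = field(default_factory=dict)
    objective_value: float = math.nan
    n_iterations: int = 0
    converged: bool = False
    bag_config: BagConfig | None = None

    @property
    def feature_dim(self) -> int:
        return 4 * self.window


@dataclass
class IterationRecord:
    iteration: int
    n_changed: int
    objective: float
    witnesses: tuple[int, ...]


@dataclass
class TrainingTrace:
    """Per-iteration diagnostics of the witness loop."""

    records: list[IterationRecord] = field(default_factory=list)
    stop_reason: str = ""

    def to_rows(self) -> list[tuple[int, int, float]]:
        return [(r.iteration, r.n_changed, r.objective) for r in self.records]


def _kernel_matrix(kernel: str, gamma: float, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    if kernel == "linear":
        return linear_kernel(X, Y)
    return rbf_kernel(X, Y, gamma=gamma)


def decision_values(model: MilSvmModel, X: np.ndarray) -> np.ndarray:
    """Kernel decision function ``f(x) = sum_k alpha_k K(sv_k, x) + b``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.feature_dim:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the model's "
            f"window ({model.window} bp -> {model.feature_dim})"
        )
    K = _kernel_matrix(model.kernel, model.gamma, X, model.support_vectors)
    return K @ model.dual_coef + model.bias


def decision_value(model: MilSvmModel, x: np.ndarray) -> float:
    return float(decision_values(model, np.asarray(x, dtype=float).reshape(1, -1))[0])


def bag_score(model: MilSvmModel, bag: LabeledBag) -> tuple[float, int]:
    """Max instance decision value and its (lowest) argmax index."""
    X = _bag_matrix(model, bag)
    values = decision_values(model, X)
    idx = int(np.argmax(values))  # np.argmax returns the first maximum
    return float(values[idx]), idx


def predict_bag(model: MilSvmModel, bag: LabeledBag) -> int:
    """Bag label ``sgn max_i f(x_i)``; a score of exactly 0 maps to +1."""
    score, _ = bag_score(model, bag)
    return 1 if score >= 0 else -1


def _bag_matrix(model: MilSvmModel, bag: LabeledBag) -> np.ndarray:
    config = model.bag_config or BagConfig(window=model.window)
    if any(len(inst.sequence) != model.window for inst in bag.instances):
        raise ValueError(
            f"bag {bag.bag_id!r} has instances whose length does not match "
            f"the model's window ({model.window} bp)"
        )
    return encode_bag(bag, config)


def _regularizer(model: MilSvmModel) -> float:
    """``1/2 ||w||^2`` in kernel space from the dual coefficients."""
    K = _kernel_matrix(model.kernel, model.gamma, model.support_vectors, model.support_vectors)
    return float(0.5 * model.dual_coef @ K @ model.dual_coef)


def mil_objective(
    model: MilSvmModel,
    bags: list[LabeledBag],
    witnesses: dict[str, int],
) -> float:
    """Evaluate ``1/2 ||w||^2 + C sum_I eps_I`` at a witness assignment.

    A positive bag's slack is the hinge loss of its witness; a negative
    bag's slack is the hinge loss of its worst-violating instance (the
    single shared slack dominating its per-instance inequalities).
    """
    total_slack = 0.0
    for bag in bags:
        values = decision_values(model, _bag_matrix(model, bag))
        if bag.label == 1:
            idx = witnesses[bag.bag_id]
            if not 0 <= idx < bag.n_instances:
                raise ValueError(
                    f"witness index {idx} out of range for bag {bag.bag_id!r} "
                    f"with {bag.n_instances} instances"
                )
            total_slack += max(0.0, 1.0 - values[idx])
        else:
            total_slack += max(0.0, 1.0 + float(np.max(values)))
    return _regularizer(model) + model.C * total_slack


def _split_bags(bags: list[LabeledBag]) -> tuple[list[LabeledBag], list[LabeledBag]]:
    pos = [b for b in bags if b.label == 1]
    neg = [b for b in bags if b.label == -1]
    if not pos or not neg:
        raise ValueError("need both positive and negative bags")
    return pos, neg


def _common_window(bags: list[LabeledBag]) -> int:
    widths = {len(inst.sequence) for bag in bags for inst in bag.instances}
    if len(widths) != 1:
        raise ValueError(f"instances have mixed window widths: {sorted(widths)}")
    return widths.pop()


def _centroid_start(
    pos_X: list[np.ndarray],
    neg_X: np.ndarray,
    config: TrainingConfig,
    gamma: float,
    window: int,
) -> tuple[int, ...]:
    """Initial witnesses via the centroid convention.

    A first SVM is trained with each positive bag represented by the mean
    of its encoded instances (against every negative instance); each bag's
    initial witness is then its argmax-decision-value instance under that
    model. Training on centroids lets the shared structure across positive
    bags steer the first selection, instead of locking onto an arbitrary
    per-bag choice that the next fit would simply confirm. For
    single-instance bags the centroid is the instance itself, so the
    reduction to a standard supervised SVM is untouched.
    """
    centroids = np.stack([X.mean(axis=0) for X in pos_X])
    y = np.concatenate([np.ones(len(pos_X)), -np.ones(len(neg_X))])
    sv, coef, bias = _train_svc(np.vstack([centroids, neg_X]), y, config, gamma)
    model = MilSvmModel(
        support_vectors=sv, dual_coef=coef, bias=bias,
        kernel=config.kernel, gamma=gamma, C=config.C, window=window,
    )
    return tuple(int(np.argmax(decision_values(model, X))) for X in pos_X)


def _bag_mean_start(pos_X: list[np.ndarray]) -> tuple[int, ...]:
    """Each bag's instance closest (squared distance) to its own mean.

    A label-free per-bag start that complements the centroid start: the
    two starts tend to enter different basins of the witness local search
    (for example different registers of the same motif), and the search
    keeps whichever converges to the lower objective.
    """
    return tuple(
        int(np.argmin(((X - X.mean(axis=0)) ** 2).sum(axis=1))) for X in pos_X
    )


def _train_svc(
    X: np.ndarray, y: np.ndarray, config: TrainingConfig, gamma: float
) -> tuple[np.ndarray, np.ndarray, float]:
    svc = SVC(
        C=config.C,
        kernel="linear" if config.kernel == "linear" else "rbf",
        gamma=gamma,
        tol=1e-6,
    )
    svc.fit(X, y)
    return svc.support_vectors_.copy(), svc.dual_coef_[0].copy(), float(svc.intercept_[0])


def _fit_witness_loop(
    bags: list[LabeledBag],
    config: TrainingConfig,
    relaxed: bool,
    bag_config: BagConfig | None,
) -> tuple[MilSvmModel, TrainingTrace]:
    pos, neg = _split_bags(bags)
    window = _common_window(bags)
    enc_config = bag_config or BagConfig(window=window)
    if enc_config.window != window:
        raise ValueError(
            f"bag_config window {enc_config.window} != instance width {window}"
        )
    gamma = config.resolve_gamma(4 * window)

    pos_X = [encode_bag(b, enc_config) for b in pos]
    neg_X = np.vstack([encode_bag(b, enc_config) for b in neg])
    neg_slices = []
    offset = 0
    for b in neg:
        neg_slices.append((offset, offset + b.n_instances))
        offset += b.n_instances
    y = np.concatenate([np.ones(len(pos)), -np.ones(len(neg_X))])

    def train(assignment: tuple[int, ...]):
        Xw = np.stack([pos_X[i][assignment[i]] for i in range(len(pos))])
        sv, coef, bias = _train_svc(np.vstack([Xw, neg_X]), y, config, gamma)
        model = MilSvmModel(
            support_vectors=sv,
            dual_coef=coef,
            bias=bias,
            kernel=config.kernel,
            gamma=gamma,
            C=config.C,
            window=window,
            bag_config=enc_config,
        )
        # MIL objective at the trained assignment, reusing cached encodings.
        slack = 0.0
        for i, X in enumerate(pos_X):
            f = decision_values(model, X)
            slack += max(0.0, 1.0 - f[assignment[i]])
        f_neg = decision_values(model, neg_X)
        for lo, hi in neg_slices:
            slack += max(0.0, 1.0 + float(np.max(f_neg[lo:hi])))
        objective = _regularizer(model) + config.C * slack
        reselect = tuple(
            int(np.argmax(decision_values(model, X))) for X in pos_X
        )
        return model, objective, reselect

    def search(assignment: tuple[int, ...]):
        trace = TrainingTrace()
        seen: set[tuple[int, ...]] = set()
        best: tuple[float, MilSvmModel, tuple[int, ...]] | None = None
        prev_objective: float | None = None
        final_model: MilSvmModel | None = None
        final_objective = math.nan
        stop = ""
        n_iter = 0
        trained_assignment = assignment

        for n_iter in range(1, config.max_iter + 1):
            if relaxed and assignment in seen:
                stop = "cycle"
                final_objective, final_model, trained_assignment = best
                n_iter -= 1
                break
            seen.add(assignment)
            trained_assignment = assignment
            model, objective, reselect = train(assignment)
            n_changed = sum(a != b for a, b in zip(assignment, reselect))
            trace.records.append(
                IterationRecord(n_iter, n_changed, objective, assignment)
            )
            if best is None or objective < best[0]:
                best = (objective, model, assignment)
            if not relaxed:
                if n_changed == 0:
                    stop = "fixed-point"
                    final_model, final_objective = model, objective
                    break
            else:
                if n_changed / len(pos) <= config.witness_change_tol:
                    stop = "witness-change"
                    final_model, final_objective = model, objective
                    break
                if (
                    prev_objective is not None
                    and abs(objective - prev_objective)
                    <= config.objective_rel_tol * abs(prev_objective)
                ):
                    stop = "objective-change"
                    final_model, final_objective = model, objective
                    break
            prev_objective = objective
            assignment = reselect
        else:
            stop = "max-iter"
            if relaxed:
                final_objective, final_model, trained_assignment = best
            else:
                final_model, final_objective = model, objective

        trace.stop_reason = stop
        return final_objective, final_model, trace, n_iter, trained_assignment

    # Deterministic multi-start: a centroid start and a per-bag-mean start
    # enter different basins of the witness search (e.g. shifted registers
    # of the same motif); the run with the lower final objective wins.
    tried: set[tuple[int, ...]] = set()
    runs = []
    for start in (
        _centroid_start(pos_X, neg_X, config, gamma, window),
        _bag_mean_start(pos_X),
    ):
        if start not in tried:
            tried.add(start)
            runs.append(search(start))
    best_run = min(runs, key=lambda r: r[0])

    # Register-shift restarts: single-witness moves cannot slide the whole
    # assignment one position along the probes, so a converged solution can
    # sit one base off the optimal register. Restart the search from the
    # best assignment shifted by +/-1 instance (clamped per bag) as long as
    # a restart improves the objective.
    k_caps = [X.shape[0] - 1 for X in pos_X]
    for _ in range(4):
        improved = False
        base = best_run[4]
        for delta in (-1, 1):
            shifted = tuple(
                min(k, max(0, a + delta)) for a, k in zip(base, k_caps)
            )
            if shifted in tried:
                continue
            tried.add(shifted)
            run = search(shifted)
            if run[0] < best_run[0]:
                best_run = run
                improved = True
        if not improved:
            break

    final_objective, final_model, trace, n_iter, _ = best_run

    final_model.n_iterations = n_iter
    final_model.converged = trace.stop_reason != "max-iter"
    # The objective is the value at the assignment the final SVM was trained
    # on; the recorded witnesses are the argmax re-selection under that
    # model, so they are self-consistent in every stopping mode (the two
    # assignments coincide at an exact fixed point).
    final_model.objective_value = final_objective
    final_model.witnesses = {
        bag.bag_id: int(np.argmax(decision_values(final_model, X)))
        for bag, X in zip(pos, pos_X)
    }
    return final_model, trace


def fit_mi_svm(
    bags: list[LabeledBag],
    config: TrainingConfig = TrainingConfig(),
    bag_config: BagConfig | None = None,
) -> tuple[MilSvmModel, TrainingTrace]:
    """Classical MI-SVM: iterate until an exact witness fixed point."""
    return _fit_witness_loop(bags, config, relaxed=False, bag_config=bag_config)


def fit_md_svm(
    bags: list[LabeledBag],
    config: TrainingConfig = TrainingConfig(),
    bag_config: BagConfig | None = None,
) -> tuple[MilSvmModel, TrainingTrace]:
    """MD-SVM: the same loop under the relaxed, stabilised criterion."""
    return _fit_witness_loop(bags, config, relaxed=True, bag_config=bag_config)


def brute_force_mil_fit(
    bags: list[LabeledBag],
    config: TrainingConfig = TrainingConfig(),
    bag_config: BagConfig | None = None,
    guard: int = 10_000,
    return_all: bool = False,
):
    """Global optimum over witness assignments by exhaustive enumeration.

    With ``return_all=True`` a fourth element is returned: the list of
    ``(witness dict, objective)`` pairs for every enumerated assignment,
    which lets callers check separability or uniqueness of the optimum.
    """
    pos, neg = _split_bags(bags)
    n_assignments = math.prod(b.n_instances for b in pos)
    if n_assignments > guard:
        raise ValueError(
            f"{n_assignments} witness assignments exceed the guard ({guard})"
        )
    window = _common_window(bags)
    enc_config = bag_config or BagConfig(window=window)
    gamma = config.resolve_gamma(4 * window)
    pos_X = [encode_bag(b, enc_config) for b in pos]
    neg_X = np.vstack([encode_bag(b, enc_config) for b in neg])
    y = np.concatenate([np.ones(len(pos)), -np.ones(len(neg_X))])

    best: tuple[float, dict[str, int], MilSvmModel] | None = None
    enumerated: list[tuple[dict[str, int], float]] = []
    for combo in itertools.product(*(range(b.n_instances) for b in pos)):
        Xw = np.stack([pos_X[i][combo[i]] for i in range(len(pos))])
        sv, coef, bias = _train_svc(np.vstack([Xw, neg_X]), y, config, gamma)
        model = MilSvmModel(
            support_vectors=sv,
            dual_coef=coef,
            bias=bias,
            kernel=config.kernel,
            gamma=gamma,
            C=config.C,
            window=window,
            bag_config=enc_config,
        )
        witnesses = {bag.bag_id: idx for bag, idx in zip(pos, combo)}
        objective = mil_objective(model, bags, witnesses)
        enumerated.append((witnesses, objective))
        if best is None or objective < best[0]:
            model.witnesses = witnesses
            model.objective_value = objective
            model.converged = True
            best = (objective, witnesses, model)
    if return_all:
        return best[1], best[0], best[2], enumerated
    return best[1], best[0], best[2]


# --------------------------------------------------------------------------
# Model persistence: a versioned JSON text file.

_REQUIRED_FIELDS = (
    "format",
    "version",
    "kernel",
    "gamma",
    "C",
    "window",
    "bias",
    "dual_coef",
    "support_vectors",
    "witnesses",
    "objective_value",
    "n_iterations",
    "converged",
    "bag_config",
)


def save_model(model: MilSvmModel, path: str | os.PathLike) -> None:
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "kernel": model.kernel,
        "gamma": model.gamma,
        "C": model.C,
        "window": model.window,
        "bias": model.bias,
        "dual_coef": model.dual_coef.tolist(),
        "support_vectors": model.support_vectors.tolist(),
        "witnesses": model.witnesses,
        "objective_value": model.objective_value,
        "n_iterations": model.n_iterations,
        "converged": model.converged,
        "bag_config": {
            "window": (model.bag_config or BagConfig(window=model.window)).window,
            "step": (model.bag_config or BagConfig(window=model.window)).step,
            "probe_length": (model.bag_config or BagConfig(window=model.window)).probe_length,
            "strand_mode": (model.bag_config or BagConfig(window=model.window)).strand_mode,
        },
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=1)
        handle.write("\n")


def load_model(path: str | os.PathLike) -> MilSvmModel:
    try:
        with open(path) as handle:
            payload = json.load(handle)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not a valid model file ({exc})") from None
    for key in _REQUIRED_FIELDS:
        if key not in payload:
            raise ModelFormatError(f"{path}: missing field {key!r}")
    if payload["format"] != MODEL_FORMAT:
        raise ModelFormatError(f"{path}: unexpected format {payload['format']!r}")
    if payload["version"] != MODEL_VERSION:
        raise ModelFormatError(
            f"{path}: version {payload['version']} unsupported "
            f"(expected {MODEL_VERSION})"
        )
    bc = payload["bag_config"]
    return MilSvmModel(
        support_vectors=np.asarray(payload["support_vectors"], dtype=float),
        dual_coef=np.asarray(payload["dual_coef"], dtype=float),
        bias=float(payload["bias"]),
        kernel=payload["kernel"],
        gamma=float(payload["gamma"]),
        C=float(payload["C"]),
        window=int(payload["window"]),
        witnesses={str(k): int(v) for k, v in payload["witnesses"].items()},
        objective_value=float(payload["objective_value"]),
        n_iterations=int(payload["n_iterations"]),
        converged=bool(payload["converged"]),
        bag_config=BagConfig(
            window=int(bc["window"]),
            step=int(bc["step"]),
            probe_length=int(bc["probe_length"]),
            strand_mode=str(bc["strand_mode"]),
        ),
    )
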