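"""Distributed Network Thresholding (DNT) and hierarchical federated averaging.

Each round, every client trains from the current global parameters on its
own shard. The central server scores each returned model on a fixed
calibration set, split by attribute group: v_pa is the held-out accuracy
using only the physical attributes (digital coordinates masked), v_pd the
converse, and v their mean. The per-round scores accumulate in the
validation matrix R. A threshold policy then admits clients — all of them
(off), those with v ≥ tau (absolute), or those within a median − z·MAD band
(robust) — and the admitted models are averaged shard-size-weighted within
each routing server, then router aggregates are averaged at the central
server. With every client admitted the two-stage mean equals the flat
weighted mean exactly, so the hierarchy is an organizational layer, not a
different estimator; its value is the per-router admission bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import PA_INDICES, PD_INDICES
from .model import (
    Architecture,
    FeatureScaler,
    ModelParameters,
    TrainingConfig,
    accuracy,
    init_params,
    predict,
    train_local,
)
from .topology import Topology


@dataclass(frozen=True)
class ValidationScore:
    v_pa: float
    v_pd: float

    def __post_init__(self) -> None:
        for v in (self.v_pa, self.v_pd):
            if not (0.0 <= v <= 1.0):
                raise ValueError("sub-scores must lie in [0, 1]")

    @property
    def v(self) -> float:
        return (self.v_pa + self.v_pd) / 2.0


class ValidationMatrix:
    """Append-only rounds × clients grid of validation scores.

    Missing entries (non-participating clients) stay absent — absence is
    distinct from a zero score.
    """

    def __init__(self) -> None:
        self._rounds: list[int] = []
        self._rows: list[dict[int, ValidationScore]] = []

    def __len__(self) -> int:
        return len(self._rounds)

    @property
    def round_indices(self) -> tuple[int, ...]:
        return tuple(self._rounds)

    def append(self, round_index: int, scores: Mapping[int, ValidationScore]) -> None:
        if self._rounds and round_index <= self._rounds[-1]:
            raise ValueError(
                f"round index {round_index} not greater than {self._rounds[-1]}"
            )
        self._rounds.append(round_index)
        self._rows.append(dict(scores))

    def row(self, round_index: int) -> dict[int, ValidationScore]:
        return dict(self._rows[self._rounds.index(round_index)])

    def to_frame(self, detailed: bool = False) -> pd.DataFrame:
        """Rows = rounds, columns = clients; cells v or 'v_pa;v_pd;v'."""
        clients = sorted({c for row in self._rows for c in row})
        data = {}
        for c in clients:
            col = []
            for row in self._rows:
                s = row.get(c)
                if s is None:
                    col.append(np.nan if not detailed else "")
                elif detailed:
                    col.append(f"{s.v_pa:.6f};{s.v_pd:.6f};{s.v:.6f}")
                else:
                    col.append(s.v)
            data[f"client_{c}"] = col
        return pd.DataFrame(data, index=pd.Index(self._rounds, name="round"))


@dataclass(frozen=True)
class ThresholdPolicy:
    """Client-admission rule for DNT.

    mode 'off' admits everyone; 'absolute' admits v >= tau; 'robust' admits
    v >= median(v) - z * MAD(v) with the unscaled median absolute deviation.
    """

    mode: str = "off"
    tau: float = 0.5
    z: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in ("off", "absolute", "robust"):
            raise ValueError(f"unknown policy mode {self.mode!r}")
        if self.z < 0:
            raise ValueError("z must be >= 0")


def client_validation_score(
    params: ModelParameters,
    calib_x: np.ndarray,
    calib_y: np.ndarray,
    pa_indices: Sequence[int] = PA_INDICES,
    pd_indices: Sequence[int] = PD_INDICES,
) -> ValidationScore:
    """Held-out accuracy restricted to each attribute group.

    v_pa masks the digital coordinates to zero (the training mean, since
    features are standardized) and scores the prediction; v_pd is symmetric.
    """
    calib_x = np.asarray(calib_x, dtype=float)
    calib_y = np.asarray(calib_y, dtype=int)
    if len(calib_x) == 0:
        raise ValueError("calibration set must be non-empty")
    if len(np.unique(calib_y)) < 2:
        raise ValueError("calibration set must contain at least two classes")
    x_pa = calib_x.copy()
    x_pa[:, list(pd_indices)] = 0.0
    x_pd = calib_x.copy()
    x_pd[:, list(pa_indices)] = 0.0
    v_pa = accuracy(params, x_pa, calib_y)
    v_pd = accuracy(params, x_pd, calib_y)
    return ValidationScore(v_pa=v_pa, v_pd=v_pd)


def dnt_admit(
    scores: Mapping[int, ValidationScore], policy: ThresholdPolicy
) -> tuple[frozenset[int], bool]:
    """Admitted client ids plus a flag marking the empty-set fallback.

    An empty admitted set falls back to the single highest-scoring client
    (earliest id on ties) so aggregation always has input.
    """
    if not scores:
        raise ValueError("need at least one score")
    ids = sorted(scores)
    v = np.array([scores[i].v for i in ids])
    if policy.mode == "off":
        return frozenset(ids), False
    if policy.mode == "absolute":
        cutoff = policy.tau
    else:
        med = float(np.median(v))
        mad = float(np.median(np.abs(v - med)))
        cutoff = med - policy.z * mad
    admitted = frozenset(i for i, vi in zip(ids, v) if vi >= cutoff)
    if admitted:
        return admitted, False
    best = ids[int(np.argmax(v))]
    return frozenset({best}), True


def weighted_average(
    params_list: Sequence[ModelParameters], weights: Sequence[float]
) -> ModelParameters:
    """Coordinate-wise weighted mean of parameter vectors.

    A single input returns an exact copy (no floating-point round trip).
    """
    if len(params_list) != len(weights):
        raise ValueError("one weight per model required")
    if not params_list:
        raise ValueError("nothing to average")
    arch = params_list[0].arch
    for p in params_list:
        if p.arch != arch:
            raise ValueError("architecture mismatch")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    if len(params_list) == 1:
        return ModelParameters(flat=params_list[0].flat.copy(), arch=arch)
    stack = np.stack([p.flat for p in params_list])
    return ModelParameters(flat=np.average(stack, axis=0, weights=w), arch=arch)


def hierarchical_aggregate(
    topology: Topology,
    client_params: Mapping[int, ModelParameters],
    client_weights: Mapping[int, float],
    admitted: Iterable[int],
) -> ModelParameters:
    """Router-wise weighted average, then a central average over routers
    weighted by each router's total admitted shard size. Routers with no
    admitted client contribute nothing."""
    admitted = frozenset(admitted)
    router_params: list[ModelParameters] = []
    router_weights: list[float] = []
    for router in topology.routers:
        members = sorted(router.client_ids & admitted)
        if not members:
            continue
        w = [client_weights[c] for c in members]
        router_params.append(weighted_average([client_params[c] for c in members], w))
        router_weights.append(float(sum(w)))
    if not router_params:
        raise ValueError("no admitted client anywhere")
    return weighted_average(router_params, router_weights)


@dataclass(frozen=True)
class RoundState:
    round_index: int
    global_params: ModelParameters
    admitted: frozenset[int] = frozenset()
    fallback: bool = False
    scores: dict = field(default_factory=dict)


def round_client_seed(train_seed: int, round_index: int, client_id: int) -> int:
    """Stable per-(round, client) training seed below 2**31."""
    ss = np.random.SeedSequence((train_seed, round_index, client_id))
    return int(ss.generate_state(1)[0] % (2**31))


def run_round(
    state: RoundState,
    topology: Topology,
    shards: Mapping[int, tuple[np.ndarray, np.ndarray]],
    cfg: TrainingConfig,
    policy: ThresholdPolicy,
    calibration_set: tuple[np.ndarray, np.ndarray],
    matrix: ValidationMatrix | None = None,
) -> RoundState:
    """One federated round: local training, scoring, admission, aggregation."""
    rnd = state.round_index
    client_params: dict[int, ModelParameters] = {}
    client_weights: dict[int, float] = {}
    scores: dict[int, ValidationScore] = {}
    for cid in sorted(shards):
        x, y = shards[cid]
        local_cfg = replace(cfg, seed=round_client_seed(cfg.seed, rnd, cid))
        p = train_local(state.global_params, x, y, local_cfg)
        client_params[cid] = p
        client_weights[cid] = float(len(y))
        scores[cid] = client_validation_score(p, *calibration_set)
    admitted, fallback = dnt_admit(scores, policy)
    new_global = hierarchical_aggregate(topology, client_params, client_weights, admitted)
    if matrix is not None:
        matrix.append(rnd, scores)
    return RoundState(
        round_index=rnd + 1,
        global_params=new_global,
        admitted=admitted,
        fallback=fallback,
        scores=scores,
    )


@dataclass(frozen=True)
class FederationResult:
    final_params: ModelParameters
    matrix: ValidationMatrix
    round_log: tuple[dict, ...]
    test_accuracy: float
    scaler: FeatureScaler


def run_federation(
    topology: Topology,
    shards: Mapping[int, tuple[np.ndarray, np.ndarray]],
    calibration_set: tuple[np.ndarray, np.ndarray],
    test_set: tuple[np.ndarray, np.ndarray],
    rounds: int,
    cfg: TrainingConfig,
    policy: ThresholdPolicy,
    init_seed: int,
    scaler: FeatureScaler,
    arch: Architecture | None = None,
) -> FederationResult:
    """Run ``rounds`` federated rounds from a seeded initialization.

    All inputs are already standardized feature matrices. Deterministic:
    the same arguments reproduce the result bit for bit. The round log
    records test accuracy, the admitted set and the aggregate norm.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    arch = arch or Architecture()
    state = RoundState(round_index=0, global_params=init_params(arch, init_seed))
    matrix = ValidationMatrix()
    log: list[dict] = []
    test_x, test_y = test_set
    for _ in range(rounds):
        state = run_round(state, topology, shards, cfg, policy, calibration_set, matrix)
        log.append(
            {
                "round": state.round_index - 1,
                "admitted": sorted(state.admitted),
                "fallback": state.fallback,
                "aggregate_norm": float(np.linalg.norm(state.global_params.flat)),
                "test_accuracy": accuracy(state.global_params, test_x, test_y),
            }
        )
    return FederationResult(
        final_params=state.global_params,
        matrix=matrix,
        round_log=tuple(log),
        test_accuracy=log[-1]["test_accuracy"],
        scaler=scaler,
    )


def train_centralized(
    x: np.ndarray,
    y: np.ndarray,
    rounds: int,
    cfg: TrainingConfig,
    init_seed: int,
    arch: Architecture | None = None,
) -> ModelParameters:
    """Centralized reference: the same seeded round schedule as a federation
    whose only client (id 0) holds all the data, so the single-client
    federation collapses onto this exactly."""
    arch = arch or Architecture()
    params = init_params(arch, init_seed)
    for rnd in range(rounds):
        local_cfg = replace(cfg, seed=round_client_seed(cfg.seed, rnd, 0))
        params = train_local(params, x, y, local_cfg)
    return params
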