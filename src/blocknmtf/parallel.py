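"""Parallel execution of block-wise NMTF with bit-reproducible results.

One worker process owns one block ``X^(i,j)`` (so ``p = N*M``; ``p = 1``
degenerates to the single-process block-wise path).  Each worker holds
replicas of its row band ``U^(i)``, its column band ``V^(j)`` and the full
``S`` — ``S`` is never partitioned.  An iteration proceeds in barrier-
aligned stages: workers compute block-local partial products, the small
``k``-dimensional aggregates are reduced across workers in a fixed
ascending order and broadcast back, and every worker then updates its own
factor replicas locally from the shared aggregates.  Because replicas of a
band are updated redundantly from identical aggregate inputs, factor
bands themselves never travel between workers — only ``k x k`` (or band-
numerator) aggregates do, which is what keeps communication volume
independent of ``n`` and ``m`` wherever a dimension is not split.

Determinism contract: reductions always accumulate partials in ascending
block index (row-major for the cross term), the same order the single-
process block-wise loop uses.  Results are therefore bit-identical to
:func:`blocknmtf.blockwise.fit_blockwise` for any worker count, and
repeated runs with the same seed are bit-identical to each other.

Exchanges are mediated by the coordinator process (a star topology); the
:class:`StagePlan` records the logical source/destination pattern of each
payload for inspection and logging.
"""

from __future__ import annotations

import multiprocessing as mp
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    ConfigurationError,
    DataMatrix,
    FactorTriple,
    FitConfig,
    FitResult,
    NumericalError,
    init_factors,
    reconstruction_error,
    resolve_init_scale,
)
from .partition import BlockGrid, extract_blocks
from .blockwise import (
    _ordered_sum,
    block_update_s,
    block_update_s_orth,
    block_update_u,
    block_update_u_orth,
    block_update_v,
    block_update_v_orth,
    fit_blockwise,
)

__all__ = [
    "WorkerAssignment",
    "Exchange",
    "Stage",
    "StagePlan",
    "build_plan",
    "run_parallel",
]


@dataclass(frozen=True)
class WorkerAssignment:
    """Which block, factor-band replicas and roles a worker holds.

    Worker ids are assigned row-major: worker ``i * M + j`` owns block
    ``(i, j)``, holds replicas of ``U^(i)``, ``V^(j)`` and the full ``S``,
    and acts as the designated representative of its row band when
    ``j == 0`` (for U-side aggregates) and of its column band when
    ``i == 0`` (for V-side aggregates).
    """

    worker: int
    block: Tuple[int, int]
    u_band: int
    v_band: int
    u_representative: bool
    v_representative: bool


@dataclass(frozen=True)
class Exchange:
    """One payload movement: producer worker -> consumer workers."""

    src: int
    dests: Tuple[int, ...]
    role: str


@dataclass(frozen=True)
class Stage:
    """A barrier-aligned step: local computations, then exchanges."""

    name: str
    computes: Tuple[Tuple[int, str], ...]
    exchanges: Tuple[Exchange, ...]


@dataclass(frozen=True)
class StagePlan:
    """Ordered stages covering one full U -> V -> S iteration."""

    stages: Tuple[Stage, ...]

    def exchanges_with_role(self, prefix: str) -> List[Exchange]:
        return [
            e for st in self.stages for e in st.exchanges if e.role.startswith(prefix)
        ]

    def summary(self) -> dict:
        return {
            "stages": len(self.stages),
            "exchanges": sum(len(st.exchanges) for st in self.stages),
            "roles": sorted({e.role for st in self.stages for e in st.exchanges}),
        }


def _band_workers(N: int, M: int):
    row = [[i * M + j for j in range(M)] for i in range(N)]
    col = [[i * M + j for i in range(N)] for j in range(M)]
    return row, col


def build_plan(g: BlockGrid, p: int, variant: str = "nonorthogonal"):
    """Stage plan and worker assignment for one iteration on ``p`` workers.

    Reductions are represented as partial-payload exchanges toward a band
    representative (or worker 0 for global aggregates) followed by a
    broadcast of the reduced aggregate; band updates are purely local.
    A reduction with a single participant needs no exchange, so e.g. an
    ``N x 1`` grid moves no U-side payloads at all.
    """
    N, M = g.N, g.M
    if p != N * M and p != 1:
        raise ConfigurationError(
            f"worker count p={p} must equal N*M={N * M} (or 1)"
        )
    row_w, col_w = _band_workers(N, M)
    all_w = tuple(range(N * M))
    assignment = [
        WorkerAssignment(
            worker=i * M + j,
            block=(i, j),
            u_band=i,
            v_band=j,
            u_representative=(j == 0),
            v_representative=(i == 0),
        )
        for i in range(N)
        for j in range(M)
    ]
    if p == 1:
        return StagePlan(stages=(Stage("local", ((0, "full iteration"),), ()),)), assignment

    stages: List[Stage] = []

    def reduce_broadcast(name, partial_desc, role, groups, recipients):
        """groups: list of participant-worker lists (ascending reduce order)."""
        computes = tuple(
            (w, partial_desc) for grp in groups for w in grp
        )
        exchanges = []
        for grp, dests in zip(groups, recipients):
            if len(grp) == 1 and tuple(dests) == (grp[0],):
                continue  # single participant consuming locally: no payload moves
            head = grp[0]
            for w in grp[1:]:
                exchanges.append(Exchange(w, (head,), f"{role}_partial"))
            out = tuple(d for d in dests if d != head)
            if out:
                exchanges.append(Exchange(head, out, role))
        stages.append(Stage(name, computes, tuple(exchanges)))

    def local(name, desc):
        stages.append(Stage(name, tuple((w, desc) for w in all_w), ()))

    def u_side_aggregate(name, desc, role):
        """k x k aggregate over U row bands: local when N == 1 (every
        worker holds the full row dimension), reduced otherwise."""
        if N == 1:
            local(name, f"{desc} (local: single row band)")
        else:
            reduce_broadcast(
                name, f"{desc} (band representatives)", role,
                [[row_w[i][0] for i in range(N)]], [list(all_w)],
            )

    def v_side_aggregate(name, desc, role):
        if M == 1:
            local(name, f"{desc} (local: single column band)")
        else:
            reduce_broadcast(
                name, f"{desc} (band representatives)", role,
                [[col_w[j][0] for j in range(M)]], [list(all_w)],
            )

    if variant == "orthogonal":
        reduce_broadcast(
            "u_numerator", "X(i,j) @ (V(j) S^T)", "u_num", row_w, row_w
        )
        u_side_aggregate("u_orth_aggregate", "U(i)^T P(i)", "orth_a")
        local("u_update", "U(i) ∘ sqrt(P(i) / (U(i) A))")
        reduce_broadcast(
            "v_numerator", "X(i,j)^T @ U(i)", "v_num", col_w, col_w
        )
        v_side_aggregate("v_orth_aggregate", "V(j)^T Q(j)", "orth_b")
        local("v_update", "V(j) ∘ sqrt(Q(j) / (V(j) B))")
    else:
        v_side_aggregate("gram_v", "V(j)^T V(j)", "gram_v")
        reduce_broadcast(
            "u_numerator", "X(i,j) @ (V(j) S^T)", "u_num", row_w, row_w
        )
        local("u_update", "U(i) ∘ num / (U(i) S gram_v S^T)")
        u_side_aggregate("gram_u", "U(i)^T U(i)", "gram_u")
        reduce_broadcast(
            "v_numerator", "X(i,j)^T @ U(i)", "v_num", col_w, col_w
        )
        local("v_update", "V(j) ∘ num S / (V(j) S^T gram_u S)")
    reduce_broadcast(
        "s_cross",
        "U(i)^T X(i,j) V(j)",
        "uxv",
        [list(all_w)],
        [list(all_w)],
    )
    v_side_aggregate("gram_v_fresh", "V(j)^T V(j)", "gram_v2")
    if variant == "orthogonal":
        u_side_aggregate("gram_u_fresh", "U(i)^T U(i)", "gram_u2")
    local("s_update", "S ∘ ratio (all replicas, identical inputs)")
    return StagePlan(stages=tuple(stages)), assignment


# ---------------------------------------------------------------------------
# worker process
# ---------------------------------------------------------------------------

def _worker_main(conn, wid, i, j, N, M, Xb, U, V, S, variant, eps, max_iter, check_every):
    """SPMD worker loop; all collectives are mediated by the coordinator.

    Protocol per collective: send (key, partial-or-None), receive the
    reduced aggregate (or None when not a recipient).  At check
    iterations, band owners ship their replicas to the coordinator and
    every worker receives a stop flag.
    """
    try:
        def collective(key, partial):
            conn.send((key, partial))
            return conn.recv()

        def u_agg(key, partial):
            """Aggregate over row bands; local when there is only one."""
            return partial if N == 1 else collective(key, partial if j == 0 else None)

        def v_agg(key, partial):
            return partial if M == 1 else collective(key, partial if i == 0 else None)

        def row_reduce(key, partial):
            """Per-row-band reduction; local when each band has one block."""
            return partial if M == 1 else collective(key, partial)

        def col_reduce(key, partial):
            return partial if N == 1 else collective(key, partial)

        for it in range(1, max_iter + 1):
            if variant == "orthogonal":
                P = row_reduce("u_num", Xb @ (V @ S.T))
                A = u_agg("orth_a", U.T @ P)
                U = block_update_u_orth(U, P, A, eps)
                Q = col_reduce("v_num", Xb.T @ U) @ S
                B = v_agg("orth_b", V.T @ Q)
                V = block_update_v_orth(V, Q, B, eps)
                uxv = collective("uxv", U.T @ (Xb @ V))
                gram_v = v_agg("gram_v2", V.T @ V)
                gram_u = u_agg("gram_u2", U.T @ U)
                S = block_update_s_orth(uxv, S, gram_u, gram_v, eps)
            else:
                gram_v = v_agg("gram_v", V.T @ V)
                num_u = row_reduce("u_num", Xb @ (V @ S.T))
                U = U * num_u / np.maximum(U @ ((S @ gram_v) @ S.T), eps)
                gram_u = u_agg("gram_u", U.T @ U)
                num_v = col_reduce("v_num", Xb.T @ U) @ S
                V = V * num_v / np.maximum(V @ ((S.T @ gram_u) @ S), eps)
                uxv = collective("uxv", U.T @ (Xb @ V))
                gram_v = v_agg("gram_v2", V.T @ V)
                S = block_update_s(uxv, S, gram_u, gram_v, eps)
            if it % check_every == 0 or it == max_iter:
                conn.send(
                    (
                        "collect",
                        (
                            U if j == 0 else None,
                            V if i == 0 else None,
                            S if wid == 0 else None,
                        ),
                    )
                )
                stop = conn.recv()
                if stop:
                    break
        conn.send(("done", None))
    except Exception as exc:  # pragma: no cover - exercised only on failure
        import traceback

        conn.send(("error", f"{exc}\n{traceback.format_exc()}"))
    finally:
        conn.close()


class _Coordinator:
    """Services collectives: gathers partials, reduces in ascending block
    order, and routes aggregates back to recipient workers."""

    def __init__(self, conns, assignment, N, M):
        self.conns = conns
        self.assign = assignment
        self.N, self.M = N, M
        row_w, col_w = _band_workers(N, M)
        self.row_w, self.col_w = row_w, col_w
        self.all_w = list(range(N * M))

    def _gather(self, expect_key):
        msgs = []
        for w in self.all_w:
            key, payload = self.conns[w].recv()
            if key == "error":
                raise NumericalError(f"worker {w} failed: {payload}")
            if key != expect_key:
                raise RuntimeError(
                    f"protocol error: worker {w} sent {key!r}, expected {expect_key!r}"
                )
            msgs.append(payload)
        return msgs

    def serve(self, key):
        """Serve one collective and return nothing (results go to workers)."""
        parts = self._gather(key)
        if key in ("u_num", "v_num"):
            groups = self.row_w if key == "u_num" else self.col_w
            for grp in groups:
                reduced = _ordered_sum([parts[w] for w in grp])
                for w in grp:
                    self.conns[w].send(reduced)
        elif key == "uxv":
            order = [
                self.row_w[i][j] for i in range(self.N) for j in range(self.M)
            ]  # row-major block order == ascending worker id
            reduced = _ordered_sum([parts[w] for w in order])
            for w in self.all_w:
                self.conns[w].send(reduced)
        elif key in ("gram_u", "gram_u2", "orth_a"):
            reps = [self.row_w[i][0] for i in range(self.N)]
            reduced = _ordered_sum([parts[w] for w in reps])
            for w in self.all_w:
                self.conns[w].send(reduced)
        elif key in ("gram_v", "gram_v2", "orth_b"):
            reps = [self.col_w[j][0] for j in range(self.M)]
            reduced = _ordered_sum([parts[w] for w in reps])
            for w in self.all_w:
                self.conns[w].send(reduced)
        else:  # pragma: no cover
            raise RuntimeError(f"unknown collective {key!r}")

    def collect_factors(self, grid: BlockGrid) -> FactorTriple:
        parts = self._gather("collect")
        U = np.vstack([parts[self.row_w[i][0]][0] for i in range(self.N)])
        V = np.vstack([parts[self.col_w[j][0]][1] for j in range(self.M)])
        S = parts[0][2]
        return FactorTriple(U, S, V)

    def send_stop(self, stop: bool):
        for w in self.all_w:
            self.conns[w].send(stop)


def _collective_schedule(variant: str, N: int, M: int) -> List[str]:
    """Collectives actually exchanged per iteration; aggregates whose
    band is replicated on every worker are computed locally instead."""
    u_side = N > 1   # U-band aggregates need reduction
    v_side = M > 1
    if variant == "orthogonal":
        keys = [
            ("u_num", v_side), ("orth_a", u_side), ("v_num", u_side),
            ("orth_b", v_side), ("uxv", True), ("gram_v2", v_side),
            ("gram_u2", u_side),
        ]
    else:
        keys = [
            ("gram_v", v_side), ("u_num", v_side), ("gram_u", u_side),
            ("v_num", u_side), ("uxv", True), ("gram_v2", v_side),
        ]
    return [k for k, needed in keys if needed]


def run_parallel(
    X: DataMatrix,
    cfg: FitConfig,
    grid: BlockGrid,
    p: int,
    init: Optional[FactorTriple] = None,
) -> FitResult:
    """Block-wise factorisation on ``p`` worker processes.

    Bit-identical to :func:`fit_blockwise` on the same grid/seed for any
    valid ``p`` (the fixed reduction order makes floating-point sums
    reproducible).  ``p = 1`` runs the single-process block-wise path
    directly.
    """
    N, M = grid.N, grid.M
    if p == 1:
        return fit_blockwise(X, cfg, grid, init=init)
    if p != N * M:
        raise ConfigurationError(f"worker count p={p} must equal N*M={N * M} (or 1)")
    cfg.validate_for(X)
    if init is None:
        f0 = init_factors(X.n, X.m, cfg, scale=resolve_init_scale(X, cfg))
    else:
        f0 = init
    blocks = extract_blocks(X, grid)
    _, assignment = build_plan(grid, p, cfg.variant)
    U_bands = [f0.U[a:b] for a, b in zip(grid.row_bounds, grid.row_bounds[1:])]
    V_bands = [f0.V[a:b] for a, b in zip(grid.col_bounds, grid.col_bounds[1:])]

    # fork keeps workers usable from interactive/stdin sessions (spawn and
    # forkserver both re-execute __main__); fall back to spawn elsewhere.
    try:
        ctx = mp.get_context("fork")
    except ValueError:  # pragma: no cover - non-POSIX platforms
        ctx = mp.get_context("spawn")
    conns, procs = [], []
    try:
        for a in assignment:
            i, j = a.block
            parent, child = ctx.Pipe()
            proc = ctx.Process(
                target=_worker_main,
                args=(
                    child,
                    a.worker,
                    i,
                    j,
                    N,
                    M,
                    blocks[i][j],
                    U_bands[i].copy(),
                    V_bands[j].copy(),
                    f0.S.copy(),
                    cfg.variant,
                    cfg.epsilon,
                    cfg.max_iter,
                    cfg.check_every,
                ),
            )
            proc.start()
            child.close()
            conns.append(parent)
            procs.append(proc)

        coord = _Coordinator(conns, assignment, N, M)
        schedule = _collective_schedule(cfg.variant, N, M)
        trajectory = [reconstruction_error(X, f0)]
        factors = f0
        converged = False
        iterations = 0
        for it in range(1, cfg.max_iter + 1):
            for key in schedule:
                coord.serve(key)
            iterations = it
            if it % cfg.check_every == 0 or it == cfg.max_iter:
                factors = coord.collect_factors(grid)
                obj = reconstruction_error(X, factors)
                if not np.isfinite(obj):
                    coord.send_stop(True)
                    raise NumericalError(
                        f"objective became non-finite at iteration {it}"
                    )
                prev = trajectory[-1]
                trajectory.append(obj)
                if abs(obj - prev) / max(prev, cfg.epsilon) < cfg.tol:
                    converged = True
                    coord.send_stop(True)
                    break
                coord.send_stop(False)
        for w, conn in enumerate(conns):
            key, payload = conn.recv()
            if key == "error":
                raise NumericalError(f"worker {w} failed: {payload}")
        for proc in procs:
            proc.join(timeout=60)
    finally:
        for proc in procs:
            if proc.is_alive():
                proc.terminate()
                proc.join()
        for conn in conns:
            conn.close()

    return FitResult(
        factors=factors,
        objective_trajectory=np.asarray(trajectory),
        converged=converged,
        iterations_run=iterations,
        grid=grid,
    )
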