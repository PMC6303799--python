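"""Framework for balancing topological complexity against model error.

Candidate reduced networks are "truncation frontiers": at any junction
whose entire distal side contains no protected segment, that side can be
replaced by a Windkessel outlet.  Candidates are compositions of such
truncations, ordered by retained artery count; the optimizer simulates the
baseline once, builds each candidate with Method 1 or Method 2, simulates
it and evaluates the quantity-of-interest error, returning the feasible
candidate with the fewest arteries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .model import ValidationError, VascularNetwork
from .method1 import solve_steady, truncate_network
from .method2 import reduce_with_method2
from . import metrics as _metrics
from .solver import SimulationResult, SolverConfig, run_simulation

__all__ = [
    "QuantitySpec",
    "OptimizationOutcome",
    "enumerate_candidates",
    "evaluate_candidates",
    "select_optimal",
    "optimize_topology",
]

_METRIC_FUNCS = {
    "eps_P_avg": lambda b, r: _metrics.eps_avg(b, r, "pressure"),
    "eps_Q_avg": lambda b, r: _metrics.eps_avg(b, r, "flow"),
    "eps_P_sys": lambda b, r: _metrics.eps_extrema(b, r)[0],
    "eps_P_dia": lambda b, r: _metrics.eps_extrema(b, r)[1],
    "eps_PP": lambda b, r: _metrics.eps_extrema(b, r)[2],
    "eps_P_aug": lambda b, r: _metrics.eps_aug(b, r),
}

_VAR_FOR_METRIC = {
    "eps_P_avg": "P", "eps_P_sys": "P", "eps_P_dia": "P",
    "eps_PP": "P", "eps_P_aug": "P", "eps_Q_avg": "Q",
}


@dataclass
class QuantitySpec:
    """Quantity of interest: sites, metric (possibly a named sum), threshold."""

    sites: list                   # [(segment_id, position)]
    metric: str                   # e.g. "eps_P_avg" or "eps_P_sys+eps_P_dia"
    threshold: float              # fraction

    def __post_init__(self):
        if self.threshold < 0:
            raise ValidationError("threshold must be non-negative")
        for name in self.terms():
            if name not in _METRIC_FUNCS:
                raise ValidationError(f"unknown metric {name!r}")

    def terms(self):
        return [t.strip() for t in self.metric.split("+")]

    def evaluate(self, baseline: SimulationResult, reduced: SimulationResult):
        """Metric averaged over sites; each site sums the metric terms."""
        vals = []
        for seg_id, pos in self.sites:
            total = 0.0
            for name in self.terms():
                var = _VAR_FOR_METRIC[name]
                b = baseline.waveform(seg_id, pos, var)
                r = reduced.waveform(seg_id, pos, var)
                v = _METRIC_FUNCS[name](b, r)
                if v is None:
                    raise ValidationError(
                        f"metric {name} undefined at site ({seg_id}, {pos})"
                    )
                total += v
            vals.append(total)
        return float(np.mean(vals))


@dataclass
class OptimizationOutcome:
    best_retained_ids: list | None
    n_arteries: int | None
    achieved_error: float | None
    candidate_table: list = field(default_factory=list)
    method: int = 2
    feasible: bool = True


def _removable_sets(net: VascularNetwork, protected: set):
    """Per-junction removable distal sides (no protected segment inside)."""
    g = net.as_graph()
    inflow = net.inflow_node
    seg_nodes = {
        s.id: (net.node_of(s.id, "prox"), net.node_of(s.id, "dist"))
        for s in net.segments
    }
    basis = []
    for node in net.junction_nodes():
        gg = g.copy()
        gg.remove_node(node)
        removable = set()
        for comp in nx.connected_components(gg):
            if inflow in comp:
                continue
            segs = {
                sid for sid, (a, b) in seg_nodes.items()
                if (a in comp or b in comp)
            }
            removable |= segs
        if removable and not (removable & protected):
            basis.append(frozenset(removable))
    # deduplicate nested/equal sets
    return sorted(set(basis), key=lambda s: (len(s), sorted(s)))


def enumerate_candidates(net: VascularNetwork, protected_ids) -> list:
    """Ordered candidate retained-sets, smallest artery count first.

    Each candidate is a sorted list of retained segment ids.  The baseline
    itself (nothing removed) is always the last candidate.
    """
    protected = set(protected_ids)
    all_ids = {s.id for s in net.segments}
    unknown = protected - all_ids
    if unknown:
        raise ValidationError(f"unknown protected ids {sorted(unknown)}")
    inflow_sid = net.topology[net.inflow_node][0][0]
    protected = protected | {inflow_sid}
    # protected sites must be reachable from the inflow
    g = net.as_graph()
    for sid in protected:
        if not nx.has_path(g, net.inflow_node, net.node_of(sid, "dist")):
            raise ValidationError(f"protected segment {sid} unreachable")

    basis = _removable_sets(net, protected)
    seen = set()
    candidates = []
    for k in range(len(basis) + 1):
        for combo in itertools.combinations(basis, k):
            removed = frozenset().union(*combo) if combo else frozenset()
            retained = frozenset(all_ids - removed)
            if retained in seen:
                continue
            seen.add(retained)
            candidates.append(sorted(retained))
    candidates.sort(key=lambda ids: (len(ids), ids))
    return candidates


def evaluate_candidates(
    net: VascularNetwork,
    qspec: QuantitySpec,
    method: int = 2,
    config: SolverConfig | None = None,
    candidates: list | None = None,
):
    """Simulate baseline and every candidate; return (table, baseline_result).

    table rows: (candidate_index, retained_ids, n_arteries, error or None,
    failure_reason or None).
    """
    config = config or SolverConfig()
    protected = {sid for sid, _ in qspec.sites}
    if candidates is None:
        candidates = enumerate_candidates(net, protected)
    ss = solve_steady(net)

    # baseline needs waveforms at QoI sites and at all possible cut faces
    cut_sites = set()
    for cand in candidates:
        from .method1 import _cut_faces

        try:
            for sid, end, node, bcs in _cut_faces(net, cand):
                cut_sites.add((sid, 1.0 if end == "dist" else 0.0))
        except ValidationError:
            pass
    base_cfg = SolverConfig(
        dx_target=config.dx_target, cfl=config.cfl,
        max_cycles=config.max_cycles, periodicity_tol=config.periodicity_tol,
        output_sites=sorted(set(qspec.sites) | cut_sites),
        dt_override=config.dt_override,
    )
    baseline = run_simulation(net, base_cfg)

    table = []
    for k, cand in enumerate(candidates):
        if set(cand) == {s.id for s in net.segments}:
            table.append((k, cand, len(cand), 0.0, None))
            continue
        try:
            if method == 1:
                reduced = truncate_network(net, ss, cand)
            else:
                reduced = reduce_with_method2(
                    net, baseline, cand, config=config, ss=ss
                )
            red_cfg = SolverConfig(
                dx_target=config.dx_target, cfl=config.cfl,
                max_cycles=config.max_cycles,
                periodicity_tol=config.periodicity_tol,
                output_sites=list(qspec.sites),
                dt_override=config.dt_override,
            )
            result = run_simulation(reduced, red_cfg)
            err = qspec.evaluate(baseline, result)
            table.append((k, cand, len(cand), err, None))
        except Exception as exc:  # infeasible candidate: recorded, not fatal
            table.append((k, cand, len(cand), None, str(exc)))
    return table, baseline


def select_optimal(table, threshold: float):
    """Smallest feasible candidate; ties broken by lowest achieved error."""
    feasible = [row for row in table if row[3] is not None and row[3] <= threshold]
    if not feasible:
        return None
    return min(feasible, key=lambda r: (r[2], r[3]))


def optimize_topology(
    net: VascularNetwork,
    qspec: QuantitySpec,
    method: int = 2,
    config: SolverConfig | None = None,
    exhaustive: bool = True,
) -> OptimizationOutcome:
    """Find the network with the fewest arteries meeting the threshold.

    With ``exhaustive`` (default) every candidate is evaluated and
    minimality is certified; otherwise candidates are evaluated in
    ascending size and the first feasible one is returned.
    """
    candidates = enumerate_candidates(net, {sid for sid, _ in qspec.sites})
    if exhaustive:
        table, _ = evaluate_candidates(net, qspec, method, config, candidates)
        best = select_optimal(table, qspec.threshold)
        if best is None:
            return OptimizationOutcome(
                best_retained_ids=None, n_arteries=None, achieved_error=None,
                candidate_table=table, method=method, feasible=False,
            )
        return OptimizationOutcome(
            best_retained_ids=best[1], n_arteries=best[2],
            achieved_error=best[3], candidate_table=table, method=method,
        )
    # first-feasible ascending scan
    table = []
    for cand in candidates:
        sub, _ = evaluate_candidates(net, qspec, method, config, [cand])
        table.extend(sub)
        row = sub[0]
        if row[3] is not None and row[3] <= qspec.threshold:
            return OptimizationOutcome(
                best_retained_ids=row[1], n_arteries=row[2],
                achieved_error=row[3], candidate_table=table, method=method,
            )
    return OptimizationOutcome(
        best_retained_ids=None, n_arteries=None, achieved_error=None,
        candidate_table=table, method=method, feasible=False,
    )
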