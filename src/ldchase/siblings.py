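"""Attribute crossovers to the shared reference sample or to test embryos.

Every test embryo is compared against the same monosomic reference, so a
crossover that truly occurred on the reference chromosome reappears — at
nearly the same position and with the same direction — in *every* sibling's
callset.  Scanning the merged, sorted list of calls for clusters of nearly
coincident, same-direction calls from a majority of embryos therefore
isolates the reference's own crossovers; the cluster means are assigned to
the reference and the member calls are subtracted, leaving each embryo's
private crossovers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ldchase.scan import CrossoverCall

DEFAULT_CLUSTER_BP = 5_000_000  # region size l


@dataclass(frozen=True)
class CrossoverCluster:
    """A group of coincident same-direction calls from k of n embryos."""

    members: tuple[tuple[str, CrossoverCall], ...]  # (embryo_id, call)
    n_embryos: int

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def mean_position(self) -> float:
        return float(np.mean([c.midpoint for _, c in self.members]))

    @property
    def span(self) -> float:
        pos = [c.midpoint for _, c in self.members]
        return max(pos) - min(pos)

    @property
    def support(self) -> float:
        """lambda_i = k_i / n, the fraction of embryos showing the call."""
        return self.size / self.n_embryos

    @property
    def kappa_min(self) -> float:
        return min(c.kappa for _, c in self.members)

    @property
    def direction(self) -> str:
        return self.members[0][1].direction


@dataclass(frozen=True)
class AttributedCallset:
    """Reference-attributed clusters plus each embryo's residual calls."""

    reference_clusters: tuple[CrossoverCluster, ...]
    residual: Mapping[str, tuple[CrossoverCall, ...]]
    discarded: tuple[tuple[str, CrossoverCall], ...]  # in-cluster duplicates


def cluster_crossovers(
    callsets: Mapping[str, Sequence[CrossoverCall]],
    region_bp: float = DEFAULT_CLUSTER_BP,
) -> list[CrossoverCluster]:
    """Find majority clusters of coincident calls across sibling embryos.

    The merged sorted call list is scanned for clusters of k calls from k
    distinct embryos within a region of size ``region_bp``, for k = n,
    n-1, ..., down to the smallest integer exceeding n/2.  Calls of
    opposite direction never co-cluster.  When one embryo contributes
    several calls to a candidate cluster, only the call closest to the
    cluster mean is kept (the rest stay available as private calls).
    Overlapping candidates are resolved by larger k, then smaller span,
    then leftmost position.
    """
    n = len(callsets)
    if n < 2:
        raise ValueError("clustering needs >= 2 test embryos")
    merged: list[tuple[float, str, CrossoverCall]] = sorted(
        (
            (call.midpoint, embryo, call)
            for embryo, calls in sorted(callsets.items())
            for call in calls
        ),
        key=lambda t: (t[0], t[1]),
    )
    assigned: set[int] = set()  # indices into merged
    clusters: list[CrossoverCluster] = []
    min_size = n // 2 + 1
    for target in range(n, min_size - 1, -1):
        while True:
            candidates = []
            for a in range(len(merged)):
                if a in assigned:
                    continue
                pos_a, _, call_a = merged[a]
                group = [a]
                for b in range(a + 1, len(merged)):
                    if b in assigned:
                        continue
                    pos_b, _, call_b = merged[b]
                    if pos_b - pos_a > region_bp:
                        break
                    if call_b.direction != call_a.direction:
                        continue
                    group.append(b)
                resolved = _resolve_duplicates(merged, group)
                if len(resolved) >= target:
                    resolved = resolved[:]  # distinct embryos, closest-first
                    span = merged[resolved[-1]][0] - merged[resolved[0]][0]
                    candidates.append((len(resolved), -span, -pos_a, resolved, group))
            if not candidates:
                break
            candidates.sort(reverse=True)
            _, _, _, resolved, group = candidates[0]
            clusters.append(
                CrossoverCluster(
                    members=tuple(
                        (merged[i][1], merged[i][2]) for i in sorted(resolved)
                    ),
                    n_embryos=n,
                )
            )
            # resolved members leave the pool; unresolved duplicates remain
            assigned.update(resolved)
    clusters.sort(key=lambda c: c.mean_position)
    return clusters


def _resolve_duplicates(
    merged: list[tuple[float, str, CrossoverCall]], group: list[int]
) -> list[int]:
    """Keep, per embryo, the call closest to the candidate cluster mean."""
    mean = float(np.mean([merged[i][0] for i in group]))
    best: dict[str, int] = {}
    for i in group:
        pos, embryo, _ = merged[i]
        cur = best.get(embryo)
        if cur is None or abs(pos - mean) < abs(merged[cur][0] - mean):
            best[embryo] = i
    return sorted(best.values())


def attribute(
    callsets: Mapping[str, Sequence[CrossoverCall]],
    clusters: Sequence[CrossoverCluster],
) -> AttributedCallset:
    """Assign cluster means to the reference; subtract members per embryo.

    Cluster members that were dropped as in-cluster duplicates (several
    calls from one embryo inside one cluster region) are *not* removed from
    the embryo's list — only actual members are subtracted.
    """
    member_ids: set[tuple[str, int]] = {
        (embryo, id(call)) for cl in clusters for embryo, call in cl.members
    }
    residual: dict[str, tuple[CrossoverCall, ...]] = {}
    for embryo, calls in callsets.items():
        residual[embryo] = tuple(
            c for c in calls if (embryo, id(c)) not in member_ids
        )
    return AttributedCallset(
        reference_clusters=tuple(clusters),
        residual=residual,
        discarded=(),
    )
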