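"""Planted-partition bipartite benchmark generators.

Three scenario families of binary bipartite graphs with known community
structure, used to score how well a detection pipeline recovers planted
communities:

* ``equal_3_3`` -- three equal-sized communities in both modes; mode-1
  third s draws its within-community ties from mode-2 third s.
* ``unequal_3_2`` -- three communities in mode 1 but only two in mode 2:
  the three mode-1 thirds target the first half, the middle third, and the
  second half of mode 2 respectively.  The middle third straddles the
  half boundary, so the best non-overlapping mode-2 partition is the
  half-split: three communities in mode 1, two in mode 2.
* ``unequal_2_10`` -- two communities in mode 1 and ten in mode 2: twenty
  equal mode-1 subsections alternate between *anchors*, which target one
  tenth of mode 2, and *bridges*, which target the two one-thirtieth strips
  flanking the boundary between consecutive tenths.  No bridge spans the
  boundary between the fifth and sixth tenths, so the mode-1 halves form two
  planted communities while the mode-2 tenths form ten.

Every mode-1 node receives exactly ``d = round(density * n2)`` ties, so the
realized overall density is exact and only mode-2 degrees fluctuate.  Each
node draws Binomial(d, p_within) ties uniformly without replacement from its
designated mode-2 region and the remainder uniformly from outside it.  If a
region is smaller than the within draw (possible for the narrow bridge
regions of ``unequal_2_10`` at high density), the excess spills uniformly
outside, with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graph import BipartiteGraph, Partition

logger = logging.getLogger(__name__)

__all__ = ["SCENARIOS", "ScenarioConfig", "GroundTruth", "generate"]

SCENARIOS = ("equal_3_3", "unequal_3_2", "unequal_2_10")

#: (n1 divisor, n2 divisor) per scenario
_DIVISORS = {"equal_3_3": (3, 6), "unequal_3_2": (3, 6), "unequal_2_10": (20, 30)}


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator parameters for one planted-partition scenario.

    Defaults are the small-design values: 60 x 120 nodes, overall density
    0.125 and within-community tie probability 0.9.  The large design uses
    600 x 1200 at density 0.025 (see :func:`large_config`).
    """

    scenario: str
    n1: int = 60
    n2: int = 120
    density: float = 0.125
    p_within: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if not 0 <= self.p_within <= 1:
            raise ValueError("p_within must be in [0, 1]")
        div1, div2 = _DIVISORS[self.scenario]
        if self.n1 % div1 or self.n2 % div2:
            raise ValueError(
                f"{self.scenario} needs n1 divisible by {div1} and n2 divisible by {div2}")

    @property
    def d(self) -> int:
        """Fixed mode-1 degree, round(density * n2)."""
        return int(round(self.density * self.n2))


def small_config(scenario: str, seed: int = 0) -> ScenarioConfig:
    """The 60 x 120, density-0.125 design."""
    return ScenarioConfig(scenario, 60, 120, 0.125, 0.9, seed)


def large_config(scenario: str, seed: int = 0) -> ScenarioConfig:
    """The 600 x 1200, density-0.025 design."""
    return ScenarioConfig(scenario, 600, 1200, 0.025, 0.9, seed)


@dataclass(frozen=True)
class GroundTruth:
    """Planted community labels for both modes."""

    labels1: Partition
    labels2: Partition


def _regions(config: ScenarioConfig) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Designated mode-2 region per mode-1 node, plus planted labels.

    Returns (region per mode-1 subsection indexed per node, labels1, labels2).
    """
    n1, n2 = config.n1, config.n2
    nodes2 = np.arange(n2)
    if config.scenario == "equal_3_3":
        sub = np.arange(n1) // (n1 // 3)
        regions = [nodes2[s * (n2 // 3):(s + 1) * (n2 // 3)] for s in range(3)]
        per_node = [regions[s] for s in sub]
        labels1 = sub
        labels2 = nodes2 // (n2 // 3)
    elif config.scenario == "unequal_3_2":
        sub = np.arange(n1) // (n1 // 3)
        regions = [nodes2[: n2 // 2],                      # first half
                   nodes2[n2 // 3: 2 * n2 // 3],           # middle third
                   nodes2[n2 // 2:]]                       # second half
        per_node = [regions[s] for s in sub]
        labels1 = sub
        labels2 = (nodes2 >= n2 // 2).astype(np.int64)     # the optimal half-split
    else:  # unequal_2_10
        tenth, thirtieth = n2 // 10, n2 // 30
        sub = np.arange(n1) // (n1 // 20)
        regions = []
        for s in range(20):
            t = s // 2  # tenth index 0..9
            if s % 2 == 0:  # anchor: the whole tenth
                regions.append(nodes2[t * tenth:(t + 1) * tenth])
            elif t in (4, 9):
                # no bridge across the half boundary (tenths 5|6) and none past
                # tenth 10: stay inside the own tenth's last two thirtieths
                end = (t + 1) * tenth
                regions.append(nodes2[end - 2 * thirtieth: end])
            else:  # bridge: one thirtieth on each side of the boundary t|t+1
                bnd = (t + 1) * tenth
                regions.append(nodes2[bnd - thirtieth: bnd + thirtieth])
        per_node = [regions[s] for s in sub]
        labels1 = (sub >= 10).astype(np.int64)             # the two halves
        labels2 = nodes2 // tenth                          # the ten tenths
    return per_node, labels1, labels2


def generate(config: ScenarioConfig) -> tuple[BipartiteGraph, GroundTruth]:
    """Draw one planted-partition bipartite graph with its ground truth.

    Deterministic given ``config.seed``; the realized density always equals
    ``config.density`` exactly (fixed mode-1 degrees).
    """
    d = config.d
    if d < 1:
        raise ValueError("density too low: fixed mode-1 degree rounds to 0")
    if d > config.n2:
        raise ValueError("density too high: fixed mode-1 degree exceeds n2")
    per_node, labels1, labels2 = _regions(config)
    rng = np.random.default_rng(config.seed)
    edges: list[tuple[int, int]] = []
    spilled = 0
    outside_cache: dict[bytes, np.ndarray] = {}
    for i in range(config.n1):
        region = per_node[i]
        key = region.tobytes()
        if key not in outside_cache:
            outside_cache[key] = np.setdiff1d(np.arange(config.n2), region)
        outside = outside_cache[key]
        n_in = int(rng.binomial(d, config.p_within))
        if n_in > region.size:  # region saturated: spill the excess outside
            spilled += n_in - region.size
            n_in = region.size
        n_out = d - n_in
        if n_out > outside.size:
            raise ValueError("degree exceeds available targets outside the region")
        targets_in = rng.choice(region, size=n_in, replace=False)
        targets_out = rng.choice(outside, size=n_out, replace=False)
        edges.extend((i, int(j)) for j in np.concatenate([targets_in, targets_out]))
    if spilled:
        logger.warning("%s seed=%d: %d within-region draws spilled outside saturated regions",
                       config.scenario, config.seed, spilled)
    graph = BipartiteGraph(config.n1, config.n2, frozenset(edges))
    assert graph.m == config.n1 * d
    return graph, GroundTruth(Partition(labels1), Partition(labels2))
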