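"""Coalescent simulation engine and null-distribution machinery.

This is the significance engine of the pipeline: a Kingman coalescent with
piecewise-constant population size (a domestication-style bottleneck is the
motivating case), infinite-sites mutation, and no intra-locus recombination.
Conventions follow Hudson's ms so published demographies port directly:
time is measured in units of 4*N0 generations backwards from the present,
sizes are relative to N0, and theta = 4*N0*mu per locus. With these
conventions k lineages coalesce at rate k*(k-1)/x(t), the expected pairwise
coalescence time at x = 1 is 0.5, E[S] = theta * a1 and E[pi] = theta.

Simulated genealogies carry known ancestral states, so Fu & Li statistics on
simulated replicates are perfectly polarized. Null distributions are sorted,
NA-dropped (replicates with S = 0 cannot yield the test statistics), and
reproducible: the run seed deterministically spawns one substream per
replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .alignments import HaplotypeMatrix
from .neutrality import NeutralityConstants, neutrality_constants

STATISTICS = ("tajima_d", "fu_li_d", "fu_li_f", "S", "pi_hat")


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-constant size history in ms conventions.

    ``epochs`` is a tuple of (start_time, relative_size) pairs with strictly
    increasing start times; the first epoch starts at 0. The bottleneck
    convenience constructor records (t_d, t_b, x_b, x_a): a bottleneck of
    relative size x_b starting (backwards) at t_d, lasting t_b, with
    ancestral relative size x_a. Bottleneck severity k = x_b / t_b — the
    maize domestication simulations in the motivating study used k = 2.45.
    """

    epochs: tuple[tuple[float, float], ...] = ((0.0, 1.0),)
    t_d: float | None = None
    t_b: float | None = None
    x_b: float | None = None
    x_a: float | None = None

    def __post_init__(self) -> None:
        times = [t for t, _ in self.epochs]
        if times != sorted(set(times)) or times[0] != 0.0:
            raise ValueError("epoch times must start at 0 and strictly increase")
        if any(x <= 0 for _, x in self.epochs):
            raise ValueError("relative sizes must be positive")

    @classmethod
    def constant(cls, x: float = 1.0) -> "DemographicModel":
        return cls(epochs=((0.0, x),))

    @classmethod
    def bottleneck(cls, t_d: float, t_b: float, x_b: float,
                   x_a: float = 1.0) -> "DemographicModel":
        if t_d < 0 or t_b <= 0 or x_b <= 0:
            raise ValueError("bottleneck needs t_d >= 0, t_b > 0, x_b > 0")
        epochs = ((0.0, 1.0), (t_d, x_b), (t_d + t_b, x_a))
        if t_d == 0.0:
            epochs = ((0.0, x_b), (t_b, x_a))
        return cls(epochs=epochs, t_d=t_d, t_b=t_b, x_b=x_b, x_a=x_a)

    @property
    def severity(self) -> float | None:
        """k = x_b / t_b (ratio of bottleneck size to duration)."""
        if self.x_b is None or self.t_b is None:
            return None
        return self.x_b / self.t_b

    def size_at(self, t: float) -> float:
        x = self.epochs[0][1]
        for start, size in self.epochs:
            if t >= start:
                x = size
            else:
                break
        return x

    def boundaries(self) -> list[float]:
        return [t for t, _ in self.epochs if t > 0.0]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings: sample size, theta per locus, replicates, seed."""

    n: int
    theta: float
    reps: int = 1
    seed: int = 0
    fixed_s: int | None = None  # condition on S instead of theta when set

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be >= 4")
        if self.theta <= 0 and self.fixed_s is None:
            raise ValueError("theta must be > 0")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass
class Genealogy:
    """A realized coalescent tree: node times, leaf bitmasks, branch lengths."""

    n: int
    node_times: np.ndarray
    parent_times: np.ndarray  # NaN for the root
    leaf_masks: list[int]

    @property
    def tmrca(self) -> float:
        return float(np.max(self.node_times))

    def branch_nodes_and_lengths(self) -> tuple[np.ndarray, np.ndarray]:
        lengths = self.parent_times - self.node_times
        keep = ~np.isnan(lengths)
        return np.flatnonzero(keep), lengths[keep]

    @property
    def total_branch_length(self) -> float:
        _, lengths = self.branch_nodes_and_lengths()
        return float(np.sum(lengths))


def simulate_genealogy(
    sample_pops: Sequence[str],
    pop_models: dict[str, DemographicModel],
    merges: Sequence[tuple[float, str, str]] = (),
    rng: np.random.Generator | None = None,
) -> Genealogy:
    """Structured Kingman coalescent without migration.

    Each sampled lineage starts in the population named in ``sample_pops``;
    lineages coalesce only within their current population, at rate
    k*(k-1)/x_p(t). A merge event (t, src, dst) moves all of src's lineages
    into dst at time t (a clean population split viewed backwards). All
    populations must ultimately merge so a single MRCA exists.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = len(sample_pops)
    if n < 2:
        raise ValueError("need >= 2 sampled lineages")
    for p in set(sample_pops):
        if p not in pop_models:
            raise ValueError(f"no demographic model for population {p!r}")
    merges = sorted(merges)

    node_times = np.zeros(2 * n - 1)
    parent_times = np.full(2 * n - 1, np.nan)
    leaf_masks: list[int] = [1 << i for i in range(n)] + [0] * (n - 1)
    active: dict[str, list[int]] = {}
    for i, p in enumerate(sample_pops):
        active.setdefault(p, []).append(i)

    boundary_times = sorted(
        {t for m in pop_models.values() for t in m.boundaries()}
        | {t for t, _, _ in merges}
    )
    t = 0.0
    next_node = n
    merge_idx = 0
    while sum(len(v) for v in active.values()) > 1:
        while merge_idx < len(merges) and merges[merge_idx][0] <= t:
            _, src, dst = merges[merge_idx]
            if src in active:
                active.setdefault(dst, []).extend(active.pop(src))
            merge_idx += 1
        pops = [p for p, v in active.items() if len(v) >= 2]
        rates = np.array(
            [len(active[p]) * (len(active[p]) - 1) / pop_models[p].size_at(t)
             for p in pops]
        )
        total_rate = float(rates.sum())
        tb = next((b for b in boundary_times if b > t), math.inf)
        if total_rate > 0:
            wait = rng.exponential(1.0 / total_rate)
        else:
            wait = math.inf
        if t + wait < tb:
            t += wait
            p = pops[int(rng.choice(len(pops), p=rates / total_rate))] \
                if len(pops) > 1 else pops[0]
            lineages = active[p]
            i, j = rng.choice(len(lineages), size=2, replace=False)
            u, v = lineages[int(i)], lineages[int(j)]
            node_times[next_node] = t
            parent_times[u] = parent_times[v] = t
            leaf_masks[next_node] = leaf_masks[u] | leaf_masks[v]
            lineages.remove(u)
            lineages.remove(v)
            lineages.append(next_node)
            next_node += 1
        else:
            if math.isinf(tb):
                raise RuntimeError(
                    "lineages stranded in unmergeable populations"
                )
            t = tb
    return Genealogy(n=n, node_times=node_times, parent_times=parent_times,
                     leaf_masks=leaf_masks)


def mutate(
    genealogy: Genealogy,
    theta: float,
    rng: np.random.Generator,
    fixed_s: int | None = None,
) -> HaplotypeMatrix:
    """Drop infinite-sites mutations on a genealogy.

    The mutation count is Poisson(theta * total branch length) (or exactly
    ``fixed_s``); each mutation lands on a branch with probability
    proportional to its length, at a position uniform on (0, 1), and every
    leaf below the branch carries the derived state (1).
    """
    nodes, lengths = genealogy.branch_nodes_and_lengths()
    total = float(np.sum(lengths))
    if fixed_s is not None:
        m = int(fixed_s)
    else:
        m = int(rng.poisson(theta * total))
    n = genealogy.n
    if m == 0:
        return HaplotypeMatrix(n, np.empty(0), np.empty((0, n), dtype=np.int8))
    cum = np.cumsum(lengths)
    branch_idx = np.searchsorted(cum, rng.random(m) * total, side="right")
    branch_idx = np.minimum(branch_idx, len(nodes) - 1)
    positions = rng.random(m)
    order = np.argsort(positions)
    positions = positions[order]
    branch_idx = branch_idx[order]
    uniq = np.concatenate(([True], np.diff(positions) > 0))
    positions, branch_idx = positions[uniq], branch_idx[uniq]
    derived = np.zeros((len(positions), n), dtype=np.int8)
    for row, b in enumerate(branch_idx):
        mask = genealogy.leaf_masks[nodes[b]]
        for i in range(n):
            if mask >> i & 1:
                derived[row, i] = 1
    return HaplotypeMatrix(n, positions, derived)


def simulate_replicate(
    config: SimConfig,
    model: DemographicModel,
    rng: np.random.Generator,
) -> HaplotypeMatrix:
    """One infinite-sites replicate under a single-population demography."""
    gen = simulate_genealogy(["pop"] * config.n, {"pop": model}, rng=rng)
    return mutate(gen, config.theta, rng, fixed_s=config.fixed_s)


@dataclass
class NullDistribution:
    """Sorted simulated values of one statistic, with generation metadata."""

    statistic: str
    values: np.ndarray
    na_count: int
    config: SimConfig
    model: DemographicModel

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))

    @property
    def size(self) -> int:
        return len(self.values)


def _replicate_stats(counts: np.ndarray, n: int,
                     c: NeutralityConstants) -> dict[str, float]:
    """All five statistics from a vector of derived-allele counts.

    Mirrors the per-matrix functions in the neutrality module but reuses the
    precomputed constants; polarization is perfect by construction.
    """
    s = len(counts)
    if s == 0:
        return {"S": 0.0, "pi_hat": 0.0, "tajima_d": math.nan,
                "fu_li_d": math.nan, "fu_li_f": math.nan}
    d = counts.astype(float)
    pi_hat = float(np.sum(d * (n - d)) / (n * (n - 1) / 2.0))
    eta = s
    eta_e = int(np.sum(counts == 1))
    td = (pi_hat - s / c.a1) / math.sqrt(c.e1 * s + c.e2 * s * (s - 1))
    fld = (eta - c.a1 * eta_e) / math.sqrt(c.u_d * eta + c.v_d * eta**2)
    flf = (pi_hat - eta_e) / math.sqrt(c.u_f * eta + c.v_f * eta**2)
    return {"S": float(s), "pi_hat": pi_hat, "tajima_d": td,
            "fu_li_d": fld, "fu_li_f": flf}


def replicate_seeds(seed: int, reps: int) -> list[np.random.SeedSequence]:
    """Deterministic per-replicate substreams (parallelization-safe)."""
    return np.random.SeedSequence(seed).spawn(reps)


def simulate_null(
    config: SimConfig,
    model: DemographicModel,
    statistics: Iterable[str] = STATISTICS,
) -> dict[str, NullDistribution]:
    """Simulate null distributions of the requested statistics.

    Fu & Li statistics use the simulator's known ancestral states (perfect
    polarization). Replicates with S = 0 are NA for the test statistics and
    are excluded from the sorted values but counted.
    """
    stats = list(statistics)
    unknown = set(stats) - set(STATISTICS)
    if unknown:
        raise ValueError(f"unknown statistics {sorted(unknown)}")
    c = neutrality_constants(config.n)
    collected: dict[str, list[float]] = {s: [] for s in stats}
    na: dict[str, int] = {s: 0 for s in stats}
    for child in replicate_seeds(config.seed, config.reps):
        rng = np.random.default_rng(child)
        matrix = simulate_replicate(config, model, rng)
        vals = _replicate_stats(matrix.derived_counts(), config.n, c)
        for s in stats:
            v = vals[s]
            if math.isnan(v):
                na[s] += 1
            else:
                collected[s].append(v)
    out = {}
    for s in stats:
        if not collected[s]:
            raise ValueError(
                f"all replicates NA for {s!r}: theta too small"
            )
        out[s] = NullDistribution(
            statistic=s, values=np.asarray(collected[s]), na_count=na[s],
            config=config, model=model,
        )
    return out


def percentile_of(value: float, distribution: np.ndarray | Sequence[float]) -> float:
    """Mid-rank percentile of ``value`` in a sorted distribution.

    100 * (count below + 0.5 * count equal) / size. Values beyond the range
    map to 0 or 100; ties take the middle rank.
    """
    values = np.asarray(distribution, dtype=float)
    if values.size == 0:
        raise ValueError("empty distribution")
    lo = int(np.searchsorted(values, value, side="left"))
    hi = int(np.searchsorted(values, value, side="right"))
    return 100.0 * (lo + 0.5 * (hi - lo)) / values.size


def critical_values(
    distribution: np.ndarray | Sequence[float],
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Empirical two-tailed critical values (linear interpolation).

    Returns the alpha/2 and 1-alpha/2 quantiles; requires >= 40 values so the
    tails are populated. alpha = 1 degenerates to (min, max).
    """
    values = np.asarray(distribution, dtype=float)
    if values.size < 40:
        raise ValueError("distribution too small for critical values (< 40)")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if alpha == 1.0:
        import warnings

        warnings.warn("alpha = 1 gives degenerate (min, max) bounds",
                      stacklevel=2)
        return float(values.min()), float(values.max())
    lower = float(np.quantile(values, alpha / 2.0))
    upper = float(np.quantile(values, 1.0 - alpha / 2.0))
    return lower, upper


def write_ms(matrices: Sequence[HaplotypeMatrix], path, header: str = "zeascan") -> None:
    """Write replicates in ms haplotype format (``//``/``segsites``/``positions``)."""
    with open(path, "w") as fh:
        fh.write(f"{header}\n\n")
        for m in matrices:
            fh.write("//\n")
            fh.write(f"segsites: {m.num_sites}\n")
            if m.num_sites:
                fh.write("positions: "
                         + " ".join(f"{p:.5f}" for p in m.positions) + "\n")
                for i in range(m.n):
                    fh.write("".join(str(int(x)) for x in m.derived[:, i]) + "\n")
            fh.write("\n")
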