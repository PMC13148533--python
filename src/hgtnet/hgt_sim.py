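"""Forward stochastic simulation of HGT on a taxon network, at sequence level.

Each taxon carries a mobilome of ``L`` bp partitioned into elements of
``L_e`` bp.  Element transfer donor -> recipient is a Poisson process: element
e moves from taxon i to taxon j at rate rho_ij (so every bp of the recipient
is overwritten at per-bp rate rho_ij, matching the model's rate definition),
copying the donor's current element sequence over the recipient's.  Every
base of every node mutates at rate 1 (time is measured in mutation-rate
units), substituting one of the three other bases uniformly.  Between
transfer events, per-node substitution counts are drawn Poisson(L * dt) with
uniform positions — exactly equivalent to per-base exponential clocks and far
faster.

A configured hub is simulated as a real node but excluded from match
extraction: it represents unobserved mediator taxa.  The simulator doubles as
the brute-force oracle for the analytic MLD model and, through
:func:`generate_synthetic_mlds`, as the generator of noisy model-drawn MLD
fixtures for fitting experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .match_core import (
    GenomeRecord,
    InputError,
    find_maximal_exact_matches,
    intersect_to_multimatch,
)
from .mld_stats import MLD, bin_edges_for
from .hgt_model import TaxonNetwork, total_mld

__all__ = [
    "ResourceError",
    "SimConfig",
    "SimResult",
    "simulate",
    "apply_mutations",
    "codes_to_str",
    "match_lengths",
    "pooled_match_lengths",
    "generate_synthetic_mlds",
    "scale_for_head_count",
]

HUB_NAME = "hub"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ResourceError(RuntimeError):
    """Raised when a simulation would exceed its configured event budget."""


@dataclass
class SimConfig:
    """Simulation settings; time is in units of the mutation rate (mu = 1)."""

    network: TaxonNetwork
    L: int = 100_000
    L_e: int = 5_000
    T: float = 1.0
    seed: int = 0
    min_len: int = 25
    replicates: int = 1
    max_events: int = 2_000_000

    def __post_init__(self) -> None:
        if self.L <= 0 or self.L_e <= 0 or self.L % self.L_e != 0:
            raise InputError("L must be a positive multiple of L_e")
        if self.T <= 0:
            raise InputError("T must be positive")
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")


@dataclass
class SimResult:
    """Final sequences (uint8 codes 0-3), event log and mutation counts."""

    node_names: tuple[str, ...]
    sequences: np.ndarray  # (n_nodes, L) uint8
    events: list[tuple[float, str, str, int]]  # (time, donor, recipient, element)
    n_mutations: np.ndarray  # per node

    def sequence_str(self, node: str) -> str:
        i = self.node_names.index(node)
        return codes_to_str(self.sequences[i])

    def genome_record(self, node: str) -> GenomeRecord:
        return GenomeRecord(genome_id=node, taxon=node, sequence=self.sequence_str(node))


def codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def apply_mutations(seqs: np.ndarray, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Apply Poisson(L * dt) substitutions per row, in place; returns counts.

    Substitutions replace the current base with one of the three others
    uniformly.  Duplicate positions within one batch collapse to a single
    substitution; over the short inter-event intervals used here the effect
    is far below the (already sub-percent) back-mutation correction.
    """
    seqs = np.atleast_2d(seqs)
    n, L = seqs.shape
    counts = rng.poisson(L * dt, size=n)
    for i in range(n):
        c = int(counts[i])
        if c == 0:
            continue
        pos = rng.integers(0, L, size=c)
        seqs[i, pos] = (seqs[i, pos] + rng.integers(1, 4, size=c).astype(np.uint8)) % 4
    return counts


def _node_rates(network: TaxonNetwork) -> tuple[list[str], np.ndarray]:
    """Full node list (taxa + hub if configured) and its rate matrix."""
    names = list(network.taxa)
    rho = network.rates().copy()
    if network.hub_gamma is not None:
        r0 = network.hub_rates()
        m = len(names) + 1
        full = np.zeros((m, m))
        full[:-1, :-1] = rho
        full[-1, :-1] = r0  # hub -> taxon
        if network.hub_mode == "bidirectional":
            full[:-1, -1] = r0  # taxon -> hub
        names.append(HUB_NAME)
        rho = full
    return names, rho


def simulate(config: SimConfig, rng: np.random.Generator | None = None) -> SimResult:
    """Run one replicate of the Gillespie event loop.

    Each node's mobilome starts as an independent uniform-random sequence, so
    matches above the noise floor (~log4 L^2 bp) exist only through transfer.
    Deterministic for a given seed / generator state.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    names, rho = _node_rates(config.network)
    n_nodes = len(names)
    n_elem = config.L // config.L_e

    donors, recips, rates = [], [], []
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rho[i, j] > 0:
                donors.append(i)
                recips.append(j)
                rates.append(rho[i, j] * n_elem)
    rates = np.asarray(rates, dtype=float)
    total_rate = float(rates.sum())
    probs = rates / total_rate if total_rate > 0 else None

    seqs = rng.integers(0, 4, size=(n_nodes, config.L), dtype=np.uint8)
    n_mut = np.zeros(n_nodes, dtype=np.int64)
    events: list[tuple[float, str, str, int]] = []

    t = 0.0
    while True:
        dt = rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
        step = min(dt, config.T - t)
        n_mut += apply_mutations(seqs, step, rng)
        t += dt
        if t > config.T or total_rate == 0:
            break
        if len(events) >= config.max_events:
            raise ResourceError(
                f"event cap {config.max_events} reached at t={t:.3g}; "
                "lower the rates, T, or the number of elements"
            )
        k = int(rng.choice(len(rates), p=probs))
        e = int(rng.integers(n_elem))
        lo, hi = e * config.L_e, (e + 1) * config.L_e
        seqs[recips[k], lo:hi] = seqs[donors[k], lo:hi]
        events.append((t, names[donors[k]], names[recips[k]], e))

    return SimResult(tuple(names), seqs, events, n_mut)


# ---------------------------------------------------------------------------
# Match extraction from simulated sequences
# ---------------------------------------------------------------------------


def match_lengths(
    result: SimResult,
    genus_set: Sequence[str],
    min_len: int,
) -> list[int]:
    """Lengths of maximal matches shared by all taxa of the set (hub excluded).

    For n > 2 the pairwise matches against the first taxon are intersected on
    the reference coordinates, exactly as for real genomes.
    """
    if len(genus_set) < 2:
        raise InputError("genus set must have at least two taxa")
    recs = {name: result.genome_record(name) for name in genus_set}
    ref, *others = genus_set
    if len(others) == 1:
        ms = find_maximal_exact_matches(recs[ref], recs[others[0]], min_len)
        return [m.length for m in ms]
    pairwise = {
        name: find_maximal_exact_matches(recs[ref], recs[name], min_len)
        for name in others
    }
    mms = intersect_to_multimatch(pairwise, min_len, ref)
    return [m.length for m in mms]


def pooled_match_lengths(
    config: SimConfig,
    genus_sets: Sequence[Sequence[str]],
    progress: bool = False,
) -> dict[tuple[str, ...], list[int]]:
    """Pool per-set match lengths over ``config.replicates`` seeded replicates."""
    pools: dict[tuple[str, ...], list[int]] = {tuple(s): [] for s in genus_sets}
    for child in np.random.SeedSequence(config.seed).spawn(config.replicates):
        rng = np.random.default_rng(child)
        res = simulate(config, rng=rng)
        for s in genus_sets:
            pools[tuple(s)].extend(match_lengths(res, s, config.min_len))
    return pools


# ---------------------------------------------------------------------------
# Fast generative synthetic MLDs (model curve + Poisson bin noise)
# ---------------------------------------------------------------------------


def generate_synthetic_mlds(
    network: TaxonNetwork,
    genus_sets: Sequence[Sequence[str]],
    r_min: float = 1000.0,
    expected_counts_scale: float | Sequence[float] = 1.0,
    seed: int = 0,
    r_max: float = 1e5,
    bins_per_decade: int = 20,
    n_comparisons: int = 1,
    noise: bool = True,
) -> list[MLD]:
    """Draw MLDs around the analytic model curve with Poisson bin noise.

    ``expected_counts_scale`` (scalar or one value per genus set) emulates the
    number of genome comparisons performed for each set: the effective
    comparison count is round(n_comparisons * scale), expected counts per bin
    are m_total(center) * width * comparisons, and the stored densities are
    normalized by the same comparison count — so for large scale the binned
    densities converge to the model curve.  The model is evaluated at bin
    centers, making a fit of the same model to ``noise=False`` output exactly
    self-consistent (densities then equal the model without integer rounding).
    """
    edges = bin_edges_for(r_min, r_max, bins_per_decade)
    centers = np.sqrt(edges[:-1] * edges[1:])
    widths = np.diff(edges)
    rng = np.random.default_rng(seed)
    scales = np.broadcast_to(np.asarray(expected_counts_scale, float), (len(genus_sets),))

    out = []
    for s, scale in zip(genus_sets, scales):
        n_comp = max(1, int(round(n_comparisons * float(scale))))
        curve = total_mld(network, s, centers)
        expected = curve.m_total * widths * n_comp
        counts = rng.poisson(expected) if noise else np.rint(expected).astype(np.int64)
        mld = MLD(tuple(s), r_min, edges, counts, n_comp)
        if not noise:
            # exact densities, uncorrupted by integer rounding
            mld.density = expected / widths / n_comp
        out.append(mld)
    return out


def scale_for_head_count(
    network: TaxonNetwork,
    genus_set: Sequence[str],
    r_min: float = 1000.0,
    target: float = 1e4,
    bins_per_decade: int = 20,
) -> float:
    """Scale putting ``target`` expected counts in the first bin of a set."""
    edges = bin_edges_for(r_min, r_min * 2, bins_per_decade)
    center = float(np.sqrt(edges[0] * edges[1]))
    width = float(edges[1] - edges[0])
    m = float(total_mld(network, genus_set, center).m_total[0])
    if m <= 0:
        raise InputError("model density is zero at the first bin")
    return target / (m * width)
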