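"""Study-shaped synthetic datasets with planted per-gene selection regimes.

The generator emulates a domestication contrast: a ``wild`` (ancestral)
population at a configured per-site diversity, a ``landrace`` (descendant)
population that split from it recently and passed through a bottleneck, and
a single outgroup sequence at fixed divergence with codon-aware
substitutions governed by a per-gene dN/dS.

Genealogies come from a self-contained two-deme Hudson-style coalescent
without recombination within a gene: the wild deme has relative size 1
throughout, while the landrace deme follows the classic domestication
demography of a bottleneck followed by expansion -- a large recent epoch
(``expansion_size``, back to ``expansion_time_fraction * split_time``) and
a small bottleneck epoch from there to the split.  The bottleneck epoch
size is solved analytically (from the expected pair-coalescence time) so
that the expected landrace/wild diversity ratio equals
``bottleneck_factor`` times the planted regime multiplier.  The expansion
epoch keeps the descendant site-frequency spectrum from tilting toward
intermediate frequencies, matching the near-zero mean Tajima's D that
domesticated panels show.  Mutations follow the infinite-sites model at
rate ``theta_wild / 2`` per site per unit of coalescent time.

Planted regimes:

* ``purifying`` — a severe landrace bottleneck (deep diversity loss, high
  differentiation) plus a site-frequency-spectrum skew: landrace-private
  variants are resampled toward singletons with a geometric weight, giving
  the negative Tajima's D signature of a sweep.
* ``balancing`` — a balanced haplotype class segregating in both
  populations (as an old balanced polymorphism would): intermediate
  frequency in the landrace sample (``balancing_freq_range``), lower
  frequency in the wild sample (``balancing_wild_freq_range``), marked at
  enough linked sites to raise landrace diversity to the regime's
  multiplier.  This yields elevated descendant diversity, a strongly
  positive descendant Tajima's D, and *moderate* differentiation (shared
  polymorphism keeps Hudson's FST near the genomic background, matching how
  balancing candidates present in real descendant/ancestor contrasts).
* ``neutral`` — the bottleneck alone.

Every gene stores a truth record (regime, realised per-group diversity,
realised deme size, planted omega) so downstream recovery tests are honest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import diversity_stats as ds
from . import io_formats
from .io_formats import GeneModel, HaplotypeAlignment, PopulationPartition
from .kaks import BASES, GENETIC_CODE, STOP_CODONS

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig", "gene_table", "simulate_gene", "generate_dataset",
    "simulate_neutral_alignment", "landrace_deme_size", "evolve_outgroup",
    "OUTGROUP_ID",
]

OUTGROUP_ID = "OUT"

_SENSE_CODONS = sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)

REGIMES = ("neutral", "purifying", "balancing")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the analysed panel's scale: ~20 haplotypes per group,
    ~100 pathway genes of 0.5-5 kb, ancestral per-site diversity 1e-3, a
    modest genome-wide domestication bottleneck (landrace/wild diversity
    ratio 0.8), and a recent population split (0.05 in units of 2N
    generations).  Regime multipliers plant a strong diversity reduction
    (x0.05) for purifying genes and an increase (x4) for balancing genes.
    """

    n_landrace: int = 20
    n_wild: int = 20
    genes_per_pathway: dict[str, int] = field(
        default_factory=lambda: {"SSP1": 34, "SSP2": 33, "SSP3": 33}
    )
    length_range: tuple[int, int] = (501, 4998)
    theta_wild: float = 0.001
    bottleneck_factor: float = 0.8
    split_time: float = 0.05
    expansion_time_fraction: float = 0.8
    expansion_size: float = 50.0
    purifying_sweep_age_fraction: float = 0.02
    balancing_n_classes: int = 3
    balancing_within_class_factor: float = 0.35
    outgroup_divergence: float = 0.1
    regime_counts: dict[str, int] = field(default_factory=dict)
    regimes: dict[str, str] | None = None  # explicit gene -> regime (overrides counts)
    purifying_multiplier: float = 0.05
    balancing_multiplier: float = 4.0
    purifying_sfs_skew: float = 0.5
    balancing_freq_range: tuple[float, float] = (0.4, 0.6)
    balancing_wild_freq_range: tuple[float, float] = (0.25, 0.4)
    default_omega: float = 0.2
    omega: dict[str, float] = field(default_factory=dict)
    expression_log_fpkm_mean: float = 3.0
    expression_log_fpkm_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_landrace < 2 or self.n_wild < 2:
            raise ValueError("need at least 2 haplotypes per population")
        if self.theta_wild < 0:
            raise ValueError("theta_wild must be >= 0")
        if self.outgroup_divergence < 0 or self.split_time <= 0:
            raise ValueError("divergence must be >= 0 and split_time > 0")
        if self.bottleneck_factor <= 0 or self.purifying_multiplier <= 0 or self.balancing_multiplier <= 0:
            raise ValueError("diversity multipliers must be > 0")
        lo, hi = self.length_range
        if lo < 3 or hi < lo:
            raise ValueError("invalid length range")
        if lo % 3 or hi % 3:
            raise ValueError("gene lengths must be multiples of 3")
        for r in self.regime_counts:
            if r not in REGIMES:
                raise ValueError(f"unknown regime {r!r}")
        lo_f, hi_f = self.balancing_freq_range
        if not (0 < lo_f <= hi_f < 1):
            raise ValueError("balancing frequency range must lie in (0, 1)")

    @property
    def n_genes(self) -> int:
        return sum(self.genes_per_pathway.values())


# ---------------------------------------------------------------------------
# demography calibration
# ---------------------------------------------------------------------------

def expected_pair_time(
    bottleneck_size: float, split_time: float,
    expansion_time: float = 0.0, expansion_size: float = 1.0,
) -> float:
    """Expected coalescence time of a landrace pair, in units of 2N_wild.

    The landrace deme has size ``expansion_size`` on (0, expansion_time),
    ``bottleneck_size`` on (expansion_time, split_time), and merges into the
    size-1 ancestral (wild) deme at ``split_time``.  Because the wild pair
    expectation is exactly 1, this also equals the expected landrace/wild
    diversity ratio under the infinite-sites model.
    """
    t_r, n_r, n_b = expansion_time, expansion_size, bottleneck_size
    dt = split_time - t_r
    if dt < 0:
        raise ValueError("expansion_time must not exceed split_time")
    s_r = math.exp(-t_r / n_r)
    s_b = math.exp(-dt / n_b)
    return n_r * (1.0 - s_r) + s_r * (n_b * (1.0 - s_b) + s_b * 1.0)


def landrace_deme_size(
    target_ratio: float, split_time: float,
    expansion_time: float = 0.0, expansion_size: float = 1.0,
) -> float:
    """Bottleneck-epoch deme size giving an expected diversity ratio.

    Solves ``expected_pair_time(N_b, ...) = target_ratio`` for the
    bottleneck size, calibrating the planted landrace/wild ratio.  Ratios
    at or above the no-bottleneck expectation return size 1 (increases are
    produced by the balanced-class injection, not demographically); ratios
    below the floor set by the expansion epoch are clamped with a warning.
    """
    if not 0 < target_ratio:
        raise ValueError("target ratio must be > 0")
    hi = 1.0
    if target_ratio >= expected_pair_time(hi, split_time, expansion_time, expansion_size):
        return hi
    lo = 1e-9
    floor = expected_pair_time(lo, split_time, expansion_time, expansion_size)
    if target_ratio <= floor:
        logger.warning(
            "target diversity ratio %.4g below the demographic floor %.4g; clamping",
            target_ratio, floor,
        )
        return lo
    return float(brentq(
        lambda n: expected_pair_time(n, split_time, expansion_time, expansion_size) - target_ratio,
        lo, hi, xtol=1e-12,
    ))


# ---------------------------------------------------------------------------
# genealogy and mutations
# ---------------------------------------------------------------------------

def _structured_genealogy(
    rng: np.random.Generator,
    n_l: int,
    n_w: int,
    bottleneck_size: float,
    split_time: float,
    expansion_time: float = 0.0,
    expansion_size: float = 1.0,
) -> list[tuple[frozenset[int], float]]:
    """Branches (tip set below, length) of a two-deme coalescent genealogy.

    Tips 0..n_l-1 are landrace, n_l..n_l+n_w-1 wild.  The wild deme has
    size 1 throughout; the landrace deme has size ``expansion_size`` until
    ``expansion_time``, then ``bottleneck_size`` until ``split_time``, at
    which point both demes merge into a size-1 ancestral deme.  The branch
    above the grand MRCA is not returned (mutations there are fixed in the
    whole sample and invisible).
    """
    lineages: list[tuple[frozenset[int], float, int]] = (
        [(frozenset([i]), 0.0, 0) for i in range(n_l)]
        + [(frozenset([n_l + i]), 0.0, 1) for i in range(n_w)]
    )
    branches: list[tuple[frozenset[int], float]] = []
    # epoch boundaries where the landrace coalescence rate changes
    boundaries = sorted(b for b in (expansion_time, split_time) if b > 0.0)
    t = 0.0
    merged = False
    while len(lineages) > 1:
        k0 = sum(1 for lin in lineages if lin[2] == 0)
        k1 = len(lineages) - k0
        if not merged:
            size_l = expansion_size if t < expansion_time else bottleneck_size
            rate0 = k0 * (k0 - 1) / 2.0 / size_l
            rate1 = k1 * (k1 - 1) / 2.0
            rate = rate0 + rate1
            next_boundary = min((b for b in boundaries if b > t), default=split_time)
            if rate == 0.0:
                t = next_boundary
            else:
                dt = rng.exponential(1.0 / rate)
                if t + dt >= next_boundary:
                    t = next_boundary  # rate changes here; redraw (memoryless)
                else:
                    t += dt
                    deme = 0 if rng.random() < rate0 / rate else 1
                    _coalesce(rng, lineages, branches, t, deme)
            if t >= split_time:
                merged = True
                lineages = [(tips, birth, 1) for tips, birth, _ in lineages]
            continue
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        _coalesce(rng, lineages, branches, t, 1)
    return branches


def _coalesce(rng, lineages, branches, t, deme) -> None:
    pool = [i for i, lin in enumerate(lineages) if lin[2] == deme]
    i, j = sorted(rng.choice(len(pool), size=2, replace=False))
    a, b = lineages[pool[i]], lineages[pool[j]]
    branches.append((a[0], t - a[1]))
    branches.append((b[0], t - b[1]))
    new = (a[0] | b[0], t, deme)
    for k in sorted((pool[i], pool[j]), reverse=True):
        lineages.pop(k)
    lineages.append(new)


def _kingman_genealogy(rng: np.random.Generator, n: int) -> list[tuple[frozenset[int], float]]:
    """Single-population Kingman coalescent branches for n tips."""
    lineages: list[tuple[frozenset[int], float]] = [(frozenset([i]), 0.0) for i in range(n)]
    branches: list[tuple[frozenset[int], float]] = []
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = lineages[i], lineages[j]
        branches.append((a[0], t - a[1]))
        branches.append((b[0], t - b[1]))
        lineages = [lin for idx, lin in enumerate(lineages) if idx not in (i, j)]
        lineages.append((a[0] | b[0], t))
    return branches


def _drop_mutations(
    rng: np.random.Generator,
    branches: list[tuple[frozenset[int], float]],
    theta: float,
    length: int,
    free_sites: list[int],
) -> list[tuple[int, frozenset[int]]]:
    """Poisson infinite-sites mutations: (site, carrier tip set) pairs.

    Sites are consumed from ``free_sites`` (mutated in place) so every
    segregating mutation in a gene occupies a distinct position.
    """
    if theta <= 0 or not branches:
        return []
    lengths = np.array([b[1] for b in branches])
    total = float(lengths.sum())
    n_mut = int(rng.poisson(theta / 2.0 * length * total))
    n_mut = min(n_mut, len(free_sites))
    if n_mut == 0:
        return []
    which = rng.choice(len(branches), size=n_mut, p=lengths / total)
    pick = rng.choice(len(free_sites), size=n_mut, replace=False)
    sites = [free_sites[i] for i in pick]
    for i in sorted(pick, reverse=True):
        free_sites.pop(i)
    return [(site, branches[b][0]) for site, b in zip(sites, which)]


def _random_reference(rng: np.random.Generator, length: int) -> str:
    """Random in-frame CDS of sense codons (no stops anywhere)."""
    if length % 3:
        raise ValueError("reference length must be a multiple of 3")
    idx = rng.integers(0, len(_SENSE_CODONS), size=length // 3)
    return "".join(_SENSE_CODONS[i] for i in idx)


def evolve_outgroup(
    rng: np.random.Generator, reference: str, omega: float, divergence: float
) -> str:
    """Outgroup sequence at the given expected divergence (substitutions/site).

    Single-base substitutions are proposed uniformly; synonymous proposals
    are accepted with probability min(1, 1/omega) and nonsynonymous ones
    with min(1, omega), so the realised dN/dS matches ``omega`` while the
    total accepted count is Poisson(divergence * L).  Proposals creating
    stop codons are rejected.
    """
    seq = list(reference.upper())
    length = len(seq)
    n_target = int(rng.poisson(divergence * length))
    p_nonsyn = min(1.0, omega)
    p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
    accepted = 0
    attempts = 0
    max_attempts = 200 * (n_target + 10)
    while accepted < n_target and attempts < max_attempts:
        attempts += 1
        pos = int(rng.integers(length))
        old = seq[pos]
        new = BASES[int(rng.integers(4))]
        if new == old:
            continue
        cstart = 3 * (pos // 3)
        codon = seq[cstart:cstart + 3]
        mutant = codon.copy()
        mutant[pos - cstart] = new
        c_old, c_new = "".join(codon), "".join(mutant)
        if c_new in STOP_CODONS:
            continue
        synonymous = GENETIC_CODE[c_old] == GENETIC_CODE[c_new]
        p_accept = p_syn if synonymous else p_nonsyn
        if rng.random() < p_accept:
            seq[pos] = new
            accepted += 1
    if accepted < n_target:
        logger.warning("outgroup evolution hit the proposal cap at %d/%d substitutions",
                       accepted, n_target)
    return "".join(seq)


# ---------------------------------------------------------------------------
# per-gene simulation
# ---------------------------------------------------------------------------

def _apply_purifying_skew(
    rng: np.random.Generator,
    mutations: list[tuple[int, frozenset[int]]],
    n_landrace: int,
    skew_p: float,
) -> list[tuple[int, frozenset[int]]]:
    """Resample landrace-private derived-allele counts toward singletons.

    Each landrace-private polymorphic variant with count c >= 2 has its
    count replaced by min(c, Geometric(skew_p)) and its carriers redrawn,
    biasing the landrace site-frequency spectrum toward singletons.
    """
    land = frozenset(range(n_landrace))
    out = []
    for site, carriers in mutations:
        if carriers <= land and 2 <= len(carriers) < n_landrace:
            new_c = min(len(carriers), int(rng.geometric(skew_p)))
            if new_c < len(carriers):
                carriers = frozenset(
                    int(x) for x in rng.choice(n_landrace, size=new_c, replace=False)
                )
        out.append((site, carriers))
    return out


def _inject_balanced_class(
    rng: np.random.Generator,
    n_landrace: int,
    n_wild: int,
    length: int,
    theta: float,
    extra_ratio: float,
    freq_range: tuple[float, float],
    wild_freq_range: tuple[float, float],
    free_sites: list[int],
    n_classes: int = 1,
) -> tuple[list[tuple[int, frozenset[int]]], int]:
    """Inject balanced haplotype classes shared between the populations.

    Each class has an intermediate frequency in the landrace sample (drawn
    from ``freq_range``) and a lower frequency in the wild sample
    (``wild_freq_range``); the total number of marked (linked) sites is
    chosen so the *landrace* diversity gain equals ``extra_ratio * theta``
    per site, split evenly over ``n_classes`` independent classes.  Returns
    the injected mutations (carrier sets span both populations) and the
    first class's landrace size.
    """
    if extra_ratio <= 0 or theta <= 0:
        return [], 0
    out: list[tuple[int, frozenset[int]]] = []
    c_l_first = 0
    for part in range(max(1, n_classes)):
        f_l = rng.uniform(*freq_range)
        f_w = rng.uniform(*wild_freq_range)
        c_l = max(1, min(n_landrace - 1, int(round(f_l * n_landrace))))
        c_w = max(1, min(n_wild - 1, int(round(f_w * n_wild))))
        if part == 0:
            c_l_first = c_l
        per_site = 2.0 * c_l * (n_landrace - c_l) / (n_landrace * (n_landrace - 1))
        k = int(round(extra_ratio / max(1, n_classes) * theta * length / per_site))
        k = min(k, len(free_sites))
        if k == 0:
            continue
        land_members = rng.choice(n_landrace, size=c_l, replace=False)
        wild_members = n_landrace + rng.choice(n_wild, size=c_w, replace=False)
        members = frozenset(int(x) for x in land_members) | frozenset(int(x) for x in wild_members)
        pick = rng.choice(len(free_sites), size=k, replace=False)
        sites = [free_sites[i] for i in pick]
        for i in sorted(pick, reverse=True):
            free_sites.pop(i)
        out.extend((site, members) for site in sites)
    return out, c_l_first


def _regime_params(config: SimConfig, regime: str) -> tuple[float, float, float]:
    """(bottleneck-epoch deme size, injected diversity ratio, expansion time).

    Purifying genes carry a recent hard sweep: their post-sweep epoch (the
    time in which new variation accumulates on a star-like genealogy) is
    much shorter than the demographic expansion of neutral genes, so most
    of them are invariant or carry only young singletons.
    """
    if regime == "purifying":
        t_r = config.purifying_sweep_age_fraction * config.split_time
        size = landrace_deme_size(
            config.bottleneck_factor * config.purifying_multiplier,
            config.split_time, t_r, config.expansion_size,
        )
        return size, 0.0, t_r
    t_r = config.expansion_time_fraction * config.split_time
    neutral_size = landrace_deme_size(
        config.bottleneck_factor, config.split_time, t_r, config.expansion_size
    )
    if regime == "balancing":
        # within-class (baseline) variation is itself bottlenecked -- only the
        # balanced classes escape -- so the baseline target is a fraction of
        # the neutral level and the classes make up the rest of the multiplier
        baseline = config.bottleneck_factor * config.balancing_within_class_factor
        size = landrace_deme_size(baseline, config.split_time, t_r, config.expansion_size)
        extra = config.bottleneck_factor * config.balancing_multiplier - baseline
        return size, max(0.0, extra), t_r
    return neutral_size, 0.0, t_r


def _simulate_alignment_core(
    rng: np.random.Generator,
    config: SimConfig,
    gene_id: str,
    length: int,
    regime: str,
    omega: float,
) -> tuple[str, HaplotypeAlignment, dict]:
    """Reference, alignment (ingroup + outgroup) and truth for one gene."""
    n_l, n_w = config.n_landrace, config.n_wild
    deme_size, extra_ratio, expansion_time = _regime_params(config, regime)

    reference = _random_reference(rng, length)
    branches = _structured_genealogy(
        rng, n_l, n_w, deme_size, config.split_time,
        expansion_time, config.expansion_size,
    )
    free_sites = list(range(length))
    mutations = _drop_mutations(rng, branches, config.theta_wild, length, free_sites)
    if regime == "purifying":
        mutations = _apply_purifying_skew(rng, mutations, n_l, config.purifying_sfs_skew)
    class_size = 0
    if regime == "balancing":
        injected, class_size = _inject_balanced_class(
            rng, n_l, n_w, length, config.theta_wild, extra_ratio,
            config.balancing_freq_range, config.balancing_wild_freq_range, free_sites,
            config.balancing_n_classes,
        )
        mutations = mutations + injected

    ref_enc = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    ref_codes = io_formats._ENCODE[ref_enc]
    n = n_l + n_w
    mat = np.tile(ref_codes, (n, 1))
    for site, carriers in mutations:
        derived = (int(ref_codes[site]) + 1 + int(rng.integers(3))) % 4
        mat[list(carriers), site] = derived

    outgroup_seq = evolve_outgroup(rng, reference, omega, config.outgroup_divergence)

    sample_ids = [f"L{i + 1:02d}" for i in range(n_l)] + [f"W{i + 1:02d}" for i in range(n_w)]
    decode = np.array(list(BASES), dtype="U1")
    seqs = ["".join(decode[row]) for row in mat]
    alignment = HaplotypeAlignment(
        gene_id=gene_id,
        sample_ids=sample_ids + [OUTGROUP_ID],
        sequences=seqs + [outgroup_seq],
    )

    land_ids = sample_ids[:n_l]
    wild_ids = sample_ids[n_l:]
    pi_l = ds.theta_pi(alignment, land_ids)
    pi_w = ds.theta_pi(alignment, wild_ids)
    truth = {
        "gene": gene_id,
        "regime": regime,
        "length": length,
        "omega": omega,
        "landrace_deme_size": deme_size,
        "theta_pi_landrace": pi_l,
        "theta_pi_wild": pi_w,
        "injected_class_size": class_size,
    }
    return reference, alignment, truth


def simulate_neutral_alignment(
    rng: np.random.Generator, n: int, length: int, theta: float, gene_id: str = "gene"
) -> HaplotypeAlignment:
    """Single-population neutral coalescent sample (no outgroup).

    Standard Kingman genealogy with infinite-sites mutation at ``theta/2``
    per site per unit time, so E[S] = theta * L * a_n.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if length % 3:
        raise ValueError("length must be a multiple of 3")
    reference = _random_reference(rng, length)
    branches = _kingman_genealogy(rng, n)
    free_sites = list(range(length))
    mutations = _drop_mutations(rng, branches, theta, length, free_sites)
    ref_codes = io_formats._ENCODE[np.frombuffer(reference.encode("ascii"), dtype=np.uint8)]
    mat = np.tile(ref_codes, (n, 1))
    for site, carriers in mutations:
        derived = (int(ref_codes[site]) + 1 + int(rng.integers(3))) % 4
        mat[list(carriers), site] = derived
    decode = np.array(list(BASES), dtype="U1")
    return HaplotypeAlignment(
        gene_id=gene_id,
        sample_ids=[f"S{i + 1:02d}" for i in range(n)],
        sequences=["".join(decode[row]) for row in mat],
    )


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def gene_table(config: SimConfig) -> pd.DataFrame:
    """Deterministic per-gene design table (gene, pathway, ppi, length, regime, omega).

    Pathway-position indices run 1..6 from upstream to downstream within
    each pathway; gene lengths are drawn uniformly (multiples of 3) and
    regimes are assigned by a seeded permutation unless given explicitly.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD5]))
    rows = []
    gene_no = 0
    for pathway, count in config.genes_per_pathway.items():
        for j in range(count):
            gene_no += 1
            ppi = 1 + (j * 6) // count if count else 1
            lo, hi = config.length_range
            length = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
            rows.append({
                "gene": f"g{gene_no:03d}", "pathway": pathway, "ppi": min(ppi, 6),
                "length": length,
            })
    df = pd.DataFrame(rows)

    regimes = pd.Series("neutral", index=df["gene"])
    if config.regimes is not None:
        for gene, regime in config.regimes.items():
            if regime not in REGIMES:
                raise ValueError(f"unknown regime {regime!r} for {gene}")
            regimes.loc[gene] = regime
    elif config.regime_counts:
        order = rng.permutation(len(df))
        cursor = 0
        for regime in ("purifying", "balancing"):
            k = config.regime_counts.get(regime, 0)
            for idx in order[cursor:cursor + k]:
                regimes.iloc[idx] = regime
            cursor += k
    df["regime"] = regimes.values
    df["omega"] = [config.omega.get(g, config.default_omega) for g in df["gene"]]
    return df


def simulate_gene(config: SimConfig, gene_id: str, table: pd.DataFrame | None = None):
    """Simulate one gene: (alignment incl. outgroup, truth record).

    Each gene uses an independent random stream derived from the dataset
    seed and the gene's index, so genes are independent and the whole
    dataset is reproducible gene-by-gene.
    """
    if table is None:
        table = gene_table(config)
    row = table.loc[table["gene"] == gene_id]
    if row.empty:
        raise KeyError(f"gene {gene_id!r} not in the design table")
    row = row.iloc[0]
    index = int(table.index[table["gene"] == gene_id][0])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, index]))
    _, alignment, truth = _simulate_alignment_core(
        rng, config, gene_id, int(row["length"]), row["regime"], float(row["omega"])
    )
    return alignment, truth


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def generate_dataset(config: SimConfig, out_dir: str | Path, force: bool = False) -> dict:
    """Write a complete dataset and return its manifest.

    Produces per-gene FASTA alignments (ingroup + outgroup), a merged
    haploid VCF against a written reference, partition/pathway/expression
    truth TSVs, gene models (GFF3) and a manifest with file hashes.
    Identical seeds give byte-identical outputs.
    """
    config.validate()
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")
    (out / "alignments").mkdir(parents=True, exist_ok=True)

    table = gene_table(config)
    references: dict[str, str] = {}
    truths = []
    vcf_path = out / "variants.vcf"
    contigs = [(g, int(l)) for g, l in zip(table["gene"], table["length"])]

    sample_ids = None
    first = True
    for index, row in table.iterrows():
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, int(index)]))
        reference, alignment, truth = _simulate_alignment_core(
            rng, config, row["gene"], int(row["length"]), row["regime"], float(row["omega"])
        )
        references[row["gene"]] = reference
        truths.append(truth)
        io_formats.write_fasta_alignment(alignment, out / "alignments" / f"{row['gene']}.fasta")
        ingroup = alignment.subset(alignment.sample_ids[:-1])  # outgroup not in VCF
        if sample_ids is None:
            sample_ids = ingroup.sample_ids
        io_formats.vcf_from_alignment(
            ingroup, reference, vcf_path,
            append=not first, write_header=first, contigs=contigs,
        )
        first = False

    io_formats.write_fasta_sequences(references, out / "reference.fasta")

    partition_rows = [{"sample": s, "group": "landrace" if s.startswith("L") else "wild"}
                      for s in sample_ids]
    partition_rows.append({"sample": OUTGROUP_ID, "group": "outgroup"})
    pd.DataFrame(partition_rows).to_csv(out / "partition.tsv", sep="\t", index=False)

    table[["gene", "pathway", "ppi"]].to_csv(out / "pathway.tsv", sep="\t", index=False)

    expr_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    fpkm = np.exp(expr_rng.normal(
        config.expression_log_fpkm_mean, config.expression_log_fpkm_sd, size=(len(table), 2)
    ))
    pd.DataFrame({
        "gene": table["gene"],
        "fpkm_midday": np.round(fpkm[:, 0], 4),
        "fpkm_midnight": np.round(fpkm[:, 1], 4),
    }).to_csv(out / "expression.tsv", sep="\t", index=False)

    pd.DataFrame(truths).to_csv(out / "truth.tsv", sep="\t", index=False)

    # genes placed head-to-tail along one synthetic chromosome, table order
    models = []
    cursor = 0
    for _, row in table.iterrows():
        start, end = cursor, cursor + int(row["length"])
        models.append(GeneModel(
            gene_id=row["gene"], chromosome="chr1", start=start, end=end,
            strand="+", cds_intervals=((start, end),),
        ))
        cursor = end + 2000
    io_formats.write_gene_models_gff3(models, out / "genes.gff3")

    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "n_genes": len(table),
        "config": _jsonable(asdict(config)),
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_partition_for(config: SimConfig) -> PopulationPartition:
    """Partition object matching the generator's sample naming."""
    assignment = {f"L{i + 1:02d}": "landrace" for i in range(config.n_landrace)}
    assignment.update({f"W{i + 1:02d}": "wild" for i in range(config.n_wild)})
    assignment[OUTGROUP_ID] = "outgroup"
    return PopulationPartition(assignment)
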