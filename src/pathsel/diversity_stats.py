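"""Within- and between-population diversity statistics at gene and codon scale.

Conventions
-----------
* theta_pi and theta_w are reported **per site** (the scale on which
  population resequencing studies print them, e.g. 1e-3/site); Tajima's D is
  computed from raw counts internally.
* Missing data (``N``) and gaps (``-``) are treated identically as missing.
  Pairwise deletion is used for pi (each pair compared over its own set of
  comparable sites); complete deletion (sites with no missing call in the
  subset) is used for S-based quantities so the standard neutral theory for
  S remains valid.
* An alignment subset with no segregating site has Tajima's D reported as
  the marker value ``None`` (serialised as ``INVARIANT``), never 0.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, HaplotypeAlignment, PopulationPartition
from .kaks import GENETIC_CODE, codon_str

logger = logging.getLogger(__name__)

__all__ = [
    "GeneStatRecord", "CodonStatTrack",
    "theta_pi", "watterson_theta", "tajimas_d", "hudson_fst",
    "segregating_sites", "codon_stats", "gene_stat_record",
    "harmonic_number",
]


def harmonic_number(n: int, power: int = 1) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i**power (Watterson's denominator for power=1)."""
    i = np.arange(1, n, dtype=float)
    return float(np.sum(1.0 / i**power))


@dataclass
class GeneStatRecord:
    """Per-gene, per-group summary statistics.

    ``tajimas_d`` is ``None`` when the subset is invariant (S == 0).
    ``fst`` is populated only on cross-group records (descendant rows).
    """

    gene_id: str
    group: str
    n: int
    L: int
    L_effective: int
    S: int
    theta_pi: float
    theta_w: float
    tajimas_d: float | None
    fst: float | None = None

    def __post_init__(self) -> None:
        assert self.theta_pi >= 0 and self.theta_w >= 0 and self.S >= 0
        if self.S == 0:
            assert self.tajimas_d is None, "invariant gene must carry the INVARIANT marker"
        if self.fst is not None:
            assert self.fst <= 1.0 + 1e-12


@dataclass
class CodonStatTrack:
    """Per-codon statistics for one gene.

    Vectors have length floor(L/3) (relative to the frame offset).  Tajima's
    D per codon is computed on the pooled landrace+wild sample, matching the
    convention of reporting site-level values across all lines; it is NaN
    where the codon is monomorphic.
    """

    gene_id: str
    pi_landrace: np.ndarray
    pi_wild: np.ndarray
    fst: np.ndarray
    tajimas_d: np.ndarray  # NaN = invariant codon
    effect: list[str]      # synonymous | nonsynonymous | complex | monomorphic

    @property
    def n_codons(self) -> int:
        return len(self.effect)


# ---------------------------------------------------------------------------
# core estimators
# ---------------------------------------------------------------------------

def _encoded_subset(alignment: HaplotypeAlignment, subset=None) -> np.ndarray:
    if subset is not None:
        alignment = alignment.subset(list(subset))
    return alignment.encoded()


def _pairwise_pi(enc: np.ndarray) -> float:
    """Mean per-site pairwise difference with per-pair deletion."""
    n = enc.shape[0]
    if n < 2:
        raise ValueError("theta_pi requires at least 2 sequences")
    valid = enc != MISSING
    if valid.all():
        return _pi_clean(enc)
    total = 0.0
    pairs = 0
    for i in range(n - 1):
        vi, si = valid[i], enc[i]
        for j in range(i + 1, n):
            both = vi & valid[j]
            l_ij = int(both.sum())
            pairs += 1
            if l_ij == 0:
                continue  # no comparable sites: pair contributes 0 (logged)
            d_ij = int((si[both] != enc[j][both]).sum())
            total += d_ij / l_ij
    return total / pairs


def _pi_clean(enc: np.ndarray) -> float:
    """pi for an alignment without missing data, via per-site allele counts."""
    n, L = enc.shape
    counts = np.stack([(enc == a).sum(axis=0) for a in range(4)])
    same = (counts * (counts - 1)).sum(axis=0) / 2
    diffs = n * (n - 1) / 2 - same
    return float(diffs.sum()) / (n * (n - 1) / 2) / L


def _complete_sites(enc: np.ndarray) -> np.ndarray:
    return (enc != MISSING).all(axis=0)


def _segregating(enc: np.ndarray) -> tuple[int, int]:
    """(S, L_effective) over complete-deletion sites."""
    complete = _complete_sites(enc)
    sub = enc[:, complete]
    seg = (sub != sub[0]).any(axis=0)
    return int(seg.sum()), int(complete.sum())


def _mean_pairwise_count(enc: np.ndarray) -> float:
    """Mean pairwise difference count over complete-deletion sites."""
    sub = enc[:, _complete_sites(enc)]
    n = sub.shape[0]
    counts = np.stack([(sub == a).sum(axis=0) for a in range(4)])
    same = (counts * (counts - 1)).sum(axis=0) / 2
    diffs = n * (n - 1) / 2 - same
    return float(diffs.sum()) / (n * (n - 1) / 2)


def theta_pi(alignment: HaplotypeAlignment, subset=None) -> float:
    """Nucleotide diversity per site: mean over pairs of d_ij / L_ij.

    d_ij counts differing comparable sites for pair (i, j) and L_ij the
    sites where both sequences have a called base (pairwise deletion).
    """
    return _pairwise_pi(_encoded_subset(alignment, subset))


def segregating_sites(alignment: HaplotypeAlignment, subset=None) -> tuple[int, int]:
    """(S, L_effective) under complete deletion."""
    return _segregating(_encoded_subset(alignment, subset))


def watterson_theta(alignment: HaplotypeAlignment, subset=None) -> float:
    """Watterson's estimator per site: S / (a_n * L_effective)."""
    enc = _encoded_subset(alignment, subset)
    n = enc.shape[0]
    if n < 2:
        raise ValueError("watterson_theta requires at least 2 sequences")
    s, l_eff = _segregating(enc)
    if l_eff == 0:
        return 0.0
    return s / (harmonic_number(n) * l_eff)


# Tajima (1989) normalising constants
def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = harmonic_number(n)
    a2 = harmonic_number(n, 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def _tajimas_d_counts(pi_count: float, s: int, n: int) -> float | None:
    if s == 0:
        return None
    a1 = harmonic_number(n)
    e1, e2 = _tajima_constants(n)
    return (pi_count - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


def tajimas_d(alignment: HaplotypeAlignment, subset=None) -> float | None:
    """Tajima's D from complete-deletion counts; None when invariant (S=0)."""
    enc = _encoded_subset(alignment, subset)
    n = enc.shape[0]
    if n < 2:
        raise ValueError("tajimas_d requires at least 2 sequences")
    if n < 4:
        logger.debug("tajimas_d on n=%d (< 4) sequences is poorly behaved", n)
    s, _ = _segregating(enc)
    return _tajimas_d_counts(_mean_pairwise_count(enc), s, n)


def _between_pi(enc_a: np.ndarray, enc_b: np.ndarray) -> float:
    """Mean per-site difference over all between-group pairs (pairwise deletion)."""
    va, vb = enc_a != MISSING, enc_b != MISSING
    if va.all() and vb.all():
        na, nb = enc_a.shape[0], enc_b.shape[0]
        diffs = 0.0
        for a in range(4):
            ca = (enc_a == a).sum(axis=0)
            cb = (enc_b == a).sum(axis=0)
            diffs += (ca * (nb - cb)).sum()
        return float(diffs) / (na * nb) / enc_a.shape[1]
    total, pairs = 0.0, 0
    for i in range(enc_a.shape[0]):
        for j in range(enc_b.shape[0]):
            both = va[i] & vb[j]
            pairs += 1
            l_ij = int(both.sum())
            if l_ij == 0:
                continue
            total += int((enc_a[i][both] != enc_b[j][both]).sum()) / l_ij
    return total / pairs


def hudson_fst(alignment: HaplotypeAlignment, partition: PopulationPartition,
               groups: tuple[str, str] = ("landrace", "wild")) -> float:
    """Hudson's FST = 1 - Hw/Hb between two groups.

    Hw is the mean of the two within-group per-site pi values and Hb the
    mean per-site difference over all between-group pairs.  Hb == 0 is
    defined as FST = 0; negative values are reported unclamped.
    """
    members = [partition.members_in(alignment, g) for g in groups]
    for g, m in zip(groups, members):
        if len(m) < 2:
            raise ValueError(f"hudson_fst: group {g!r} has {len(m)} sequences (need >= 2)")
    enc_a = alignment.subset(members[0]).encoded()
    enc_b = alignment.subset(members[1]).encoded()
    hw = 0.5 * (_pairwise_pi(enc_a) + _pairwise_pi(enc_b))
    hb = _between_pi(enc_a, enc_b)
    if hb == 0.0:
        return 0.0
    return 1.0 - hw / hb


def gene_stat_record(alignment: HaplotypeAlignment, subset, group: str,
                     gene_id: str | None = None) -> GeneStatRecord:
    """Bundle n, L_effective, S, theta_pi, theta_w and Tajima's D for a subset."""
    enc = _encoded_subset(alignment, subset)
    n = enc.shape[0]
    if n < 2:
        raise ValueError("gene_stat_record requires at least 2 sequences")
    s, l_eff = _segregating(enc)
    pi = _pairwise_pi(enc)
    tw = s / (harmonic_number(n) * l_eff) if l_eff else 0.0
    d = _tajimas_d_counts(_mean_pairwise_count(enc), s, n)
    return GeneStatRecord(
        gene_id=gene_id or alignment.gene_id, group=group, n=n,
        L=alignment.length, L_effective=l_eff, S=s,
        theta_pi=pi, theta_w=tw, tajimas_d=d,
    )


# ---------------------------------------------------------------------------
# codon-resolution statistics
# ---------------------------------------------------------------------------

def _codon_effect(window: np.ndarray) -> str:
    """Classify the coding effect of observed variation within one codon.

    Rows with any missing call in the window are ignored.  Classification is
    against the major observed codon: a single segregating site is
    synonymous/nonsynonymous by translation; two or more segregating sites
    are 'complex'.  A stop codon as the major haplotype is flagged complex
    with a warning (mid-CDS stop).
    """
    called = window[(window != MISSING).all(axis=1)]
    if called.shape[0] == 0:
        return "monomorphic"
    uniq, counts = np.unique(called, axis=0, return_counts=True)
    if uniq.shape[0] == 1:
        return "monomorphic"
    seg = (called != called[0]).any(axis=0).sum()
    major = uniq[np.argmax(counts)]
    major_aa = GENETIC_CODE[codon_str(major)]
    if major_aa == "*":
        logger.warning("mid-sequence stop codon in major haplotype; flagged complex")
        return "complex"
    if seg >= 2:
        return "complex"
    aas = {GENETIC_CODE[codon_str(c)] for c in uniq}
    return "synonymous" if len(aas) == 1 else "nonsynonymous"


def codon_stats(alignment: HaplotypeAlignment, partition: PopulationPartition) -> CodonStatTrack:
    """Per-codon (non-overlapping 3-bp window) diversity statistics.

    Within-group pi per codon (per site), Hudson FST per codon (0 where the
    codon shows no between-group difference), Tajima's D on the pooled
    landrace+wild sample per codon (NaN when monomorphic), and the coding
    effect of the observed variation.
    """
    if alignment.length < 3:
        raise ValueError("codon_stats requires L >= 3")
    land = partition.members_in(alignment, "landrace")
    wild = partition.members_in(alignment, "wild")
    if len(land) < 2 or len(wild) < 2:
        raise ValueError("codon_stats requires >= 2 sequences in each group")
    off = alignment.frame_offset
    n_codons = (alignment.length - off) // 3
    enc_l = alignment.subset(land).encoded()[:, off:off + 3 * n_codons]
    enc_w = alignment.subset(wild).encoded()[:, off:off + 3 * n_codons]
    enc_all = np.vstack([enc_l, enc_w])

    pi_l = np.empty(n_codons)
    pi_w = np.empty(n_codons)
    fst = np.empty(n_codons)
    taj = np.full(n_codons, np.nan)
    effects: list[str] = []
    n_pool = enc_all.shape[0]

    for c in range(n_codons):
        sl = slice(3 * c, 3 * c + 3)
        wl, ww, wa = enc_l[:, sl], enc_w[:, sl], enc_all[:, sl]
        pi_l[c] = _pairwise_pi(wl)
        pi_w[c] = _pairwise_pi(ww)
        hb = _between_pi(wl, ww)
        fst[c] = 0.0 if hb == 0.0 else 1.0 - 0.5 * (pi_l[c] + pi_w[c]) / hb
        s, _ = _segregating(wa)
        d = _tajimas_d_counts(_mean_pairwise_count(wa), s, n_pool)
        taj[c] = np.nan if d is None else d
        effects.append(_codon_effect(wa))

    return CodonStatTrack(
        gene_id=alignment.gene_id,
        pi_landrace=pi_l, pi_wild=pi_w, fst=fst, tajimas_d=taj, effect=effects,
    )
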