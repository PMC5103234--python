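"""Ka/Ks estimation by the Nei–Gojobori (NG86) counting method.

Synonymous and nonsynonymous *sites* are counted per codon as the fraction
of possible single-nucleotide changes that preserve the encoded amino acid;
*differences* between codons are classified by translation, averaging over
all minimal substitution paths for multi-hit codons (paths through stop
codons are excluded unless every path is blocked, in which case all paths
are used and the event is logged).  Proportions are Jukes–Cantor corrected.
Mutations to stop codons count as nonsynonymous in site totals.

The significance test against neutrality (Ka/Ks = 1) is an exact binomial
test of the observed nonsynonymous/synonymous difference split against the
site-count proportion, with the doubled-tail two-sided convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
from scipy import stats

from . import io_formats
from .io_formats import MISSING, HaplotypeAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "GENETIC_CODE", "CODONS", "KaKsResult",
    "codon_str", "ng86_sites", "ng86_differences", "kaks_pair",
    "kaks_significance", "consensus_sequence", "group_kaks",
]

BASES = "ACGT"
CODONS = ["".join(c) for c in product(BASES, repeat=3)]
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

# standard nuclear genetic code
_AA = (
    "KNKNTTTTRSRSIIMIQHQHPPPPRRRRLLLL"
    "EDEDAAAAGGGGVVVV*Y*YSSSS*CWCLFLF"
)
# index codon by (A,C,G,T) -> (0..3) positional digits, base-4, first pos most significant
GENETIC_CODE = {}
for _c in CODONS:
    _idx = 0
    for _b in _c:
        _idx = _idx * 4 + "ACGT".index(_b)
    GENETIC_CODE[_c] = _AA[_idx]

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")


def codon_str(encoded: np.ndarray) -> str:
    """Decode a length-3 uint8 window (0..3) to a codon string."""
    return "".join(BASES[int(b)] for b in encoded)


# ---------------------------------------------------------------------------
# NG86 site and difference counting (precomputed tables over all 64 codons)
# ---------------------------------------------------------------------------

def _sites_for_codon(codon: str) -> tuple[float, float]:
    aa = GENETIC_CODE[codon]
    sa = ss = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if GENETIC_CODE[mutant] == aa and aa != "*":
                syn += 1
        ss += syn / 3.0
        sa += (3 - syn) / 3.0
    return sa, ss


def _path_steps(codon_a: str, codon_b: str) -> tuple[float, float, bool]:
    """Average (nonsyn, syn) step counts over minimal substitution paths.

    Paths passing through stop codons at intermediate steps are excluded; if
    every path is blocked, all paths are used and the flag in the third
    element is True.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0, False
    all_paths = []
    open_paths = []
    for order in permutations(diff_pos):
        current = codon_a
        na = ns = 0
        blocked = False
        for k, pos in enumerate(order):
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if GENETIC_CODE[current] == GENETIC_CODE[nxt] and GENETIC_CODE[nxt] != "*":
                ns += 1
            else:
                na += 1
            if k < len(order) - 1 and nxt in STOP_CODONS:
                blocked = True
            current = nxt
        all_paths.append((na, ns))
        if not blocked:
            open_paths.append((na, ns))
    used = open_paths if open_paths else all_paths
    na = sum(p[0] for p in used) / len(used)
    ns = sum(p[1] for p in used) / len(used)
    return na, ns, not open_paths


_SA = np.zeros(64)
_SS = np.zeros(64)
for _c, _i in _CODON_INDEX.items():
    if _c not in STOP_CODONS:
        _SA[_i], _SS[_i] = _sites_for_codon(_c)

_NA = np.zeros((64, 64))
_NS = np.zeros((64, 64))
_STOP_ONLY_PATH = np.zeros((64, 64), dtype=bool)
for _a, _ia in _CODON_INDEX.items():
    for _b, _ib in _CODON_INDEX.items():
        na_, ns_, flag_ = _path_steps(_a, _b)
        _NA[_ia, _ib], _NS[_ia, _ib] = na_, ns_
        _STOP_ONLY_PATH[_ia, _ib] = flag_


def ng86_sites(codon_seq: str) -> tuple[float, float]:
    """Total (nonsynonymous, synonymous) site counts for a coding sequence.

    Raises on internal stop codons, naming the codon index.
    """
    if len(codon_seq) % 3:
        raise ValueError(f"sequence length {len(codon_seq)} not divisible by 3")
    codon_seq = codon_seq.upper()
    sa = ss = 0.0
    for i in range(0, len(codon_seq), 3):
        codon = codon_seq[i:i + 3]
        if set(codon) - set(BASES):
            continue  # ambiguous codon: skipped from site totals
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at codon index {i // 3}")
        idx = _CODON_INDEX[codon]
        sa += _SA[idx]
        ss += _SS[idx]
    return sa, ss


def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) difference counts between two codons."""
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    ia, ib = _CODON_INDEX[codon_a], _CODON_INDEX[codon_b]
    if _STOP_ONLY_PATH[ia, ib]:
        logger.debug("all substitution paths %s->%s pass through stops; included", codon_a, codon_b)
    return float(_NA[ia, ib]), float(_NS[ia, ib])


# ---------------------------------------------------------------------------
# pairwise Ka/Ks
# ---------------------------------------------------------------------------

@dataclass
class KaKsResult:
    """NG86 Ka/Ks for one sequence comparison.

    ``ratio`` is NaN when undefined (Ks == 0, including the 0/0 case of
    identical sequences) or when a Jukes–Cantor correction saturates.
    """

    gene_id: str
    group: str
    Ka: float
    Ks: float
    Na: float
    Ns: float
    Sa: float
    Ss: float
    saturated: bool = False
    p_vs_1: float = float("nan")

    @property
    def ratio_defined(self) -> bool:
        return not self.saturated and self.Ns > 0 and self.Ks > 0

    @property
    def ratio(self) -> float:
        if not self.ratio_defined:
            # one nonzero-Ka / zero-Ks special case: ratio 0 when Ka == 0
            if not self.saturated and self.Ka == 0.0 and self.Ks > 0:
                return 0.0
            return float("nan")
        return self.Ka / self.Ks


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return float("nan"), True
    if p == 0.0:
        return 0.0, False
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def kaks_pair(seq_a: str, seq_b: str, gene_id: str = "", group: str = "") -> KaKsResult:
    """NG86 Ka/Ks between two equal-length in-frame coding sequences.

    Site counts are averaged over the two sequences; codons containing
    ambiguity in either sequence are excluded from both sites and
    differences.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if len(seq_a) % 3:
        raise ValueError("length must be divisible by 3")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    sa = ss = na = ns = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if set(ca) - set(BASES) or set(cb) - set(BASES):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon index {i // 3}")
        ia, ib = _CODON_INDEX[ca], _CODON_INDEX[cb]
        sa += 0.5 * (_SA[ia] + _SA[ib])
        ss += 0.5 * (_SS[ia] + _SS[ib])
        na += _NA[ia, ib]
        ns += _NS[ia, ib]
    if sa + ss == 0:
        raise ValueError("no unambiguous codons to compare")
    pa = na / sa if sa > 0 else 0.0
    ps = ns / ss if ss > 0 else 0.0
    ka, sat_a = _jc_correct(pa)
    ks, sat_s = _jc_correct(ps)
    saturated = sat_a or sat_s
    if saturated:
        logger.warning("%s/%s: saturated divergence (p >= 3/4); Ka/Ks flagged", gene_id, group)
    return KaKsResult(
        gene_id=gene_id, group=group,
        Ka=0.0 if math.isnan(ka) and not sat_a else ka,
        Ks=0.0 if math.isnan(ks) and not sat_s else ks,
        Na=na, Ns=ns, Sa=sa, Ss=ss, saturated=saturated,
    )


def kaks_significance(result: KaKsResult) -> float:
    """Two-sided doubled-tail exact binomial test of the Na/Ns split.

    Under neutrality, differences fall nonsynonymous with probability
    p0 = Sa / (Sa + Ss); the test asks whether the observed integer split
    deviates from that expectation.  Fractional path-averaged counts are
    rounded to the nearest integers.
    """
    if result.Sa + result.Ss <= 0:
        raise ValueError("zero site counts")
    total = int(round(result.Na + result.Ns))
    if total == 0:
        raise ValueError("no differences to test")
    na = int(round(result.Na))
    p0 = result.Sa / (result.Sa + result.Ss)
    lower = stats.binom.cdf(na, total, p0)
    upper = stats.binom.sf(na - 1, total, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


# ---------------------------------------------------------------------------
# group-level comparison against an outgroup
# ---------------------------------------------------------------------------

def consensus_sequence(alignment: HaplotypeAlignment, subset=None,
                       reference: str | None = None) -> str:
    """Per-site majority sequence for a subset of an alignment.

    Ties are broken toward the reference allele when one is supplied and is
    among the tied states, then alphabetically.  Sites with no called base
    fall back to the reference base (or ``N``).
    """
    if subset is not None:
        alignment = alignment.subset(list(subset))
    enc = alignment.encoded()
    counts = np.stack([(enc == a).sum(axis=0) for a in range(4)])  # (4, L)
    best = counts.max(axis=0)
    ref_enc = None
    if reference is not None:
        if len(reference) != alignment.length:
            raise ValueError("reference length mismatch")
        ref_enc = io_formats._ENCODE[np.frombuffer(reference.upper().encode(), dtype=np.uint8)]
    out = []
    for pos in range(alignment.length):
        if best[pos] == 0:
            out.append(BASES[ref_enc[pos]] if ref_enc is not None and ref_enc[pos] != MISSING else "N")
            continue
        tied = [a for a in range(4) if counts[a, pos] == best[pos]]
        if len(tied) > 1 and ref_enc is not None and int(ref_enc[pos]) in tied:
            choice = int(ref_enc[pos])
            logger.debug("%s pos %d: majority tie broken toward reference", alignment.gene_id, pos)
        else:
            choice = tied[0]  # alphabetical: encoding is in ACGT order
        out.append(BASES[choice])
    return "".join(out)


def group_kaks(
    alignment: HaplotypeAlignment,
    group_samples: list[str],
    outgroup_sample: str,
    gene_id: str | None = None,
    group: str = "",
    reference: str | None = None,
    mode: str = "consensus",
) -> KaKsResult:
    """Ka/Ks of one population group against an outgroup sequence.

    ``mode='consensus'`` (default) compares the group consensus with the
    outgroup; ``mode='pairwise_mean'`` averages NG86 counts over all
    (member x outgroup) pairs.  Which sequences enter the comparison is a
    recorded convention, not something the statistic itself dictates.
    """
    gid = gene_id or alignment.gene_id
    out_seq = alignment.subset([outgroup_sample]).sequences[0]
    if mode == "consensus":
        cons = consensus_sequence(alignment, group_samples, reference=reference)
        res = kaks_pair(cons, out_seq, gene_id=gid, group=group)
    elif mode == "pairwise_mean":
        members = alignment.subset(group_samples)
        acc = None
        for seq in members.sequences:
            r = kaks_pair(seq, out_seq, gene_id=gid, group=group)
            if acc is None:
                acc = r
            else:
                acc.Na += r.Na; acc.Ns += r.Ns; acc.Sa += r.Sa; acc.Ss += r.Ss
        k = len(members.sequences)
        acc.Na /= k; acc.Ns /= k; acc.Sa /= k; acc.Ss /= k
        pa = acc.Na / acc.Sa if acc.Sa else 0.0
        ps = acc.Ns / acc.Ss if acc.Ss else 0.0
        acc.Ka, sat_a = _jc_correct(pa)
        acc.Ks, sat_s = _jc_correct(ps)
        acc.saturated = sat_a or sat_s
        res = acc
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if res.Na + res.Ns > 0:
        res.p_vs_1 = kaks_significance(res)
    return res
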