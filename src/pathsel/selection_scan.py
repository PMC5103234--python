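"""Selection classification, flanking-gene sweep scan, and the multilocus
HKA likelihood-ratio test.

Gene-level calls use joint empirical-percentile criteria on the descendant
(landrace) population:

* purifying — theta_pi and theta_w in the lower 5% of the empirical
  distribution, FST above 95% of it, and negative Tajima's D;
* balancing — theta_pi and theta_w in the upper 25%, Tajima's D in the
  upper 5%, and FST below the 90th percentile.

All threshold comparisons are strict (a percentile of exactly 5.0 fails a
"< 5%" condition; D == 0 satisfies neither sign condition) so boundary
behaviour is deterministic.  A descendant sample with no segregating site
is labelled ``invariant`` — Tajima's D does not exist there, so the
purifying conditions cannot be evaluated.

Codon-level calls compare per-codon diversity between the two populations
against a supplied genome-mean diversity, with FST and Tajima's D sign side
conditions.

The HKA test models segregating sites and outgroup divergence per locus as
independent Poisson counts and compares a neutral model (all loci share the
polymorphism/divergence proportionality) against a selection model in which
chosen loci receive a free polymorphism scaling factor k; twice the
log-likelihood difference is referred to a chi-squared distribution with
one degree of freedom per selected locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .diversity_stats import CodonStatTrack, GeneStatRecord, harmonic_number
from .io_formats import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionCall", "ClassifierThresholds", "HKADataset", "HKAResult", "SweepSummary",
    "empirical_percentile", "classify_gene", "classify_codon",
    "flanking_sweep_scan", "hka_loglik", "hka_lrt", "simulate_hka_dataset",
    "recovery_metrics",
]

LABELS = ("purifying", "balancing", "both", "none", "invariant")


@dataclass
class SelectionCall:
    """A gene- or codon-level selection label with its supporting evidence."""

    gene_id: str
    level: str  # "gene" | "codon"
    label: str
    codon_index: int | None = None
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.label in LABELS
        assert self.level in ("gene", "codon")


@dataclass
class ClassifierThresholds:
    """Percentile cutoffs for the joint empirical criteria (in percent)."""

    purifying_diversity: float = 5.0    # theta_pi and theta_w below this
    purifying_fst: float = 95.0         # FST above this
    balancing_diversity: float = 75.0   # theta_pi and theta_w above this
    balancing_d: float = 95.0           # Tajima's D above this
    balancing_fst: float = 90.0         # FST below this

    def validate(self) -> None:
        for v in (self.purifying_diversity, self.purifying_fst,
                  self.balancing_diversity, self.balancing_d, self.balancing_fst):
            if not 0 < v < 100:
                raise ValueError("percentile cutoffs must lie in (0, 100)")


def empirical_percentile(values, x: float) -> float:
    """Percentile of ``x`` within a background sample, in [0, 100].

    One occurrence of ``x`` itself is excluded from the background when
    present (a gene ranked against a distribution it belongs to should not
    count itself); remaining ties count half.  With fewer than 20 background
    values a 5% tail is not meaningful and a warning is logged.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty background distribution")
    if values.size < 20:
        logger.warning("empirical percentile over %d background values; "
                       "5%% tails are unreliable", values.size)
    less = int(np.sum(values < x))
    ties = int(np.sum(values == x))
    denom = values.size
    if ties > 0:  # leave one matching occurrence out
        ties -= 1
        denom -= 1
    if denom == 0:
        return 50.0
    return 100.0 * (less + 0.5 * ties) / denom


@dataclass
class BackgroundTables:
    """Empirical background distributions for the percentile criteria.

    By default these come from the analysed gene set itself; supply an
    external (e.g. genome-wide) table when the analysed set is expected to
    be enriched for selected genes.  ``tajimas_d`` holds only defined
    values (invariant genes carry no D and cannot be ranked).
    """

    theta_pi: np.ndarray
    theta_w: np.ndarray
    fst: np.ndarray
    tajimas_d: np.ndarray

    @classmethod
    def from_records(cls, records: list[GeneStatRecord], fsts: list[float]) -> "BackgroundTables":
        d = [r.tajimas_d for r in records if r.tajimas_d is not None]
        return cls(
            theta_pi=np.array([r.theta_pi for r in records], dtype=float),
            theta_w=np.array([r.theta_w for r in records], dtype=float),
            fst=np.array(fsts, dtype=float),
            tajimas_d=np.array(d, dtype=float),
        )


def classify_gene(
    record_landrace: GeneStatRecord,
    record_wild: GeneStatRecord,
    fst: float,
    background: BackgroundTables,
    thresholds: ClassifierThresholds | None = None,
) -> SelectionCall:
    """Joint empirical-percentile classification of one gene.

    The descendant (landrace) record supplies the diversity statistics and
    Tajima's D; ``fst`` is the landrace/wild Hudson FST.  Raises if FST is
    missing.
    """
    th = thresholds or ClassifierThresholds()
    th.validate()
    if fst is None or np.isnan(fst):
        raise ValueError(f"{record_landrace.gene_id}: missing FST")
    gene = record_landrace.gene_id

    if record_landrace.S == 0:
        return SelectionCall(gene_id=gene, level="gene", label="invariant",
                             evidence={"S": 0})

    pct_pi = empirical_percentile(background.theta_pi, record_landrace.theta_pi)
    pct_tw = empirical_percentile(background.theta_w, record_landrace.theta_w)
    pct_fst = empirical_percentile(background.fst, fst)
    d = record_landrace.tajimas_d
    pct_d = empirical_percentile(background.tajimas_d, d)
    evidence = {
        "theta_pi_pct": pct_pi, "theta_w_pct": pct_tw,
        "fst_pct": pct_fst, "tajimas_d": d, "tajimas_d_pct": pct_d,
        "diversity_change": record_landrace.theta_pi - record_wild.theta_pi,
    }

    purifying = (
        pct_pi < th.purifying_diversity
        and pct_tw < th.purifying_diversity
        and pct_fst > th.purifying_fst
        and d < 0
    )
    balancing = (
        pct_pi > th.balancing_diversity
        and pct_tw > th.balancing_diversity
        and pct_d > th.balancing_d
        and pct_fst < th.balancing_fst
    )
    if purifying:
        label = "purifying"
    elif balancing:
        label = "balancing"
    else:
        label = "none"
    return SelectionCall(gene_id=gene, level="gene", label=label, evidence=evidence)


def classify_codon(
    track: CodonStatTrack, genome_mean_diversity: float
) -> list[SelectionCall]:
    """Site-level (codon) selection calls for one gene.

    purifying: (pi_wild - pi_landrace) > genome mean diversity, FST > 0 and
    Tajima's D < 0; balancing: the diversity increase exceeds the mean with
    FST > 0 and D > 0.  Monomorphic codons yield no call.  Each call is
    annotated with the codon's coding effect.
    """
    calls = []
    for c in range(track.n_codons):
        if track.effect[c] == "monomorphic":
            continue
        d = track.tajimas_d[c]
        if np.isnan(d):
            continue
        fst = track.fst[c]
        delta = track.pi_wild[c] - track.pi_landrace[c]
        label = None
        if delta > genome_mean_diversity and fst > 0 and d < 0:
            label = "purifying"
        elif -delta > genome_mean_diversity and fst > 0 and d > 0:
            label = "balancing"
        if label is not None:
            calls.append(SelectionCall(
                gene_id=track.gene_id, level="codon", label=label, codon_index=c,
                evidence={
                    "pi_landrace": float(track.pi_landrace[c]),
                    "pi_wild": float(track.pi_wild[c]),
                    "fst": float(fst), "tajimas_d": float(d),
                    "effect": track.effect[c],
                },
            ))
    return calls


def combine_gene_and_codon_calls(
    gene_call: SelectionCall, codon_calls: list[SelectionCall]
) -> str:
    """Final gene label; ``both`` when disjoint codon sets show each signal."""
    labels = {c.label for c in codon_calls}
    if {"purifying", "balancing"} <= labels:
        return "both"
    return gene_call.label


# ---------------------------------------------------------------------------
# flanking-gene sweep scan
# ---------------------------------------------------------------------------

@dataclass
class SweepSummary:
    """Selection-label counts among the flanking genes of one focal gene."""

    gene_id: str
    n_flanking: int
    counts: dict[str, int]
    sweep_flag: bool


def flanking_sweep_scan(
    focal_gene: str,
    gene_order: list[GeneModel],
    calls: dict[str, str],
    radius: int = 10,
) -> SweepSummary:
    """Count selection labels among up to ``radius`` genes each side.

    ``gene_order`` must be sorted by (chromosome, start); only genes on the
    focal gene's chromosome enter the window, which truncates at chromosome
    ends.  The sweep flag is raised when at least one flanking gene carries
    a non-``none`` label (selected or invariant), reading fixation in a
    neighbour as sweep-consistent evidence.
    """
    index = {m.gene_id: i for i, m in enumerate(gene_order)}
    if focal_gene not in index:
        raise KeyError(f"focal gene {focal_gene!r} not in the gene order")
    i = index[focal_gene]
    chrom = gene_order[i].chromosome
    window = []
    for j in range(i - 1, max(-1, i - radius - 1), -1):
        if gene_order[j].chromosome != chrom:
            break
        window.append(gene_order[j].gene_id)
    for j in range(i + 1, min(len(gene_order), i + radius + 1)):
        if gene_order[j].chromosome != chrom:
            break
        window.append(gene_order[j].gene_id)
    counts = {label: 0 for label in LABELS}
    for g in window:
        counts[calls.get(g, "none")] += 1
    flag = any(counts[label] > 0 for label in LABELS if label != "none")
    return SweepSummary(gene_id=focal_gene, n_flanking=len(window),
                        counts=counts, sweep_flag=flag)


# ---------------------------------------------------------------------------
# multilocus HKA
# ---------------------------------------------------------------------------

@dataclass
class HKADataset:
    """Per-locus polymorphism/divergence counts for the HKA likelihood.

    S: segregating sites in the descendant sample; D: fixed differences to
    the outgroup; L: sites; n: sample sizes.  ``selected`` indexes loci
    allowed a free polymorphism scaling k in the selection model.
    """

    S: np.ndarray
    D: np.ndarray
    L: np.ndarray
    n: np.ndarray
    selected: tuple[int, ...] = ()
    locus_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        m = len(self.S)
        if not (len(self.D) == len(self.L) == len(self.n) == m):
            raise ValueError("S, D, L, n must have equal length")
        if np.any(self.S < 0) or np.any(self.D < 0) or np.any(self.L <= 0):
            raise ValueError("counts must be >= 0 and lengths > 0")
        if any(i < 0 or i >= m for i in self.selected):
            raise ValueError("selected locus index out of range")
        self.selected = tuple(sorted(set(int(i) for i in self.selected)))
        if not self.locus_ids:
            self.locus_ids = tuple(f"locus{i}" for i in range(m))

    @property
    def n_loci(self) -> int:
        return len(self.S)

    def a_n(self) -> np.ndarray:
        return np.array([harmonic_number(int(k)) for k in self.n])

    def divergence_coeff(self, include_coalescent_correction: bool = True) -> np.ndarray:
        """Within-sample contribution to the divergence expectation.

        E[D_i] = theta_i * L_i * (T + c_i) with
        c_i = (n_i + 1) / (2 * a_n * n_i) when the correction is on, 0
        otherwise.
        """
        if not include_coalescent_correction:
            return np.zeros(self.n_loci)
        a = self.a_n()
        return (self.n + 1) / (2.0 * a * self.n)


@dataclass
class HKAResult:
    statistic: float
    df: int
    p_value: float
    loglik_neutral: float
    loglik_selection: float
    T_neutral: float
    T_selection: float
    theta_neutral: np.ndarray
    theta_selection: np.ndarray
    k: dict[int, float]


_THETA_FLOOR = 1e-12


def hka_loglik(
    dataset: HKADataset,
    theta: np.ndarray,
    T: float,
    k: dict[int, float] | None = None,
    include_coalescent_correction: bool = True,
) -> float:
    """Composite Poisson log-likelihood of an HKA parameter set.

    S_i ~ Poisson(k_i * theta_i * L_i * a_{n_i}) and
    D_i ~ Poisson(theta_i * L_i * (T + c_i)); k_i = 1 for loci outside the
    selected set.  Includes the full Poisson normalisation, so values are
    comparable across nested models.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0) or T <= 0:
        raise ValueError("theta and T must be > 0")
    k_vec = np.ones(dataset.n_loci)
    for i, val in (k or {}).items():
        if i not in dataset.selected:
            raise ValueError(f"k given for non-selected locus {i}")
        if val <= 0:
            raise ValueError("k must be > 0")
        k_vec[i] = val
    a = dataset.a_n()
    c = dataset.divergence_coeff(include_coalescent_correction)
    mu_s = k_vec * theta * dataset.L * a
    mu_d = theta * dataset.L * (T + c)
    ll = np.sum(dataset.S * np.log(mu_s) - mu_s - special.gammaln(dataset.S + 1))
    ll += np.sum(dataset.D * np.log(mu_d) - mu_d - special.gammaln(dataset.D + 1))
    return float(ll)


def _profile_loglik(dataset: HKADataset, T: float, selection: bool,
                    include_cc: bool = True) -> tuple[float, np.ndarray, dict[int, float]]:
    """Log-likelihood maximised over theta (and k) at fixed T.

    Neutral loci: theta_i = (S_i + D_i) / (L_i (a_i + T + c_i)) in closed
    form.  Selected loci (selection model): theta_i = D_i / (L_i (T + c_i))
    and k_i = S_i / (theta_i L_i a_i), also closed form.
    """
    a = dataset.a_n()
    c = dataset.divergence_coeff(include_cc)
    theta = (dataset.S + dataset.D) / (dataset.L * (a + T + c))
    theta = np.maximum(theta, _THETA_FLOOR)
    k: dict[int, float] = {}
    if selection:
        for i in dataset.selected:
            th_i = max(dataset.D[i] / (dataset.L[i] * (T + c[i])), _THETA_FLOOR)
            theta[i] = th_i
            k[i] = max(dataset.S[i] / (th_i * dataset.L[i] * a[i]), _THETA_FLOOR)
    return hka_loglik(dataset, theta, T, k or None, include_cc), theta, k


def _maximise(dataset: HKADataset, selection: bool, include_cc: bool = True,
              n_grid: int = 80) -> tuple[float, float, np.ndarray, dict[int, float]]:
    """Maximise the profile likelihood over T: grid scan + bounded refinement."""
    grid = np.logspace(-3, 4, n_grid)
    values = [_profile_loglik(dataset, t, selection, include_cc)[0] for t in grid]
    best = int(np.argmax(values))
    lo = grid[max(0, best - 1)]
    hi = grid[min(len(grid) - 1, best + 1)]
    res = optimize.minimize_scalar(
        lambda u: -_profile_loglik(dataset, float(np.exp(u)), selection, include_cc)[0],
        bounds=(np.log(lo), np.log(hi)), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        raise RuntimeError(f"HKA optimisation failed: {res.message}; best T so far "
                           f"{np.exp(res.x):.4g}")
    t_hat = float(np.exp(res.x))
    ll, theta, k = _profile_loglik(dataset, t_hat, selection, include_cc)
    return ll, t_hat, theta, k


def hka_lrt(dataset: HKADataset, include_coalescent_correction: bool = True) -> HKAResult:
    """Likelihood-ratio test of the selection model against neutrality.

    With an empty selected set the models coincide and the statistic is
    exactly 0.  Requires at least one locus outside the selected set and
    at least 2 loci overall.
    """
    if dataset.n_loci < 2:
        raise ValueError("HKA requires at least 2 loci")
    if len(dataset.selected) >= dataset.n_loci:
        raise ValueError("at least one neutral locus is required")
    ll_neu, t_neu, theta_neu, _ = _maximise(dataset, selection=False,
                                            include_cc=include_coalescent_correction)
    if not dataset.selected:
        return HKAResult(
            statistic=0.0, df=0, p_value=1.0,
            loglik_neutral=ll_neu, loglik_selection=ll_neu,
            T_neutral=t_neu, T_selection=t_neu,
            theta_neutral=theta_neu, theta_selection=theta_neu, k={},
        )
    ll_sel, t_sel, theta_sel, k = _maximise(dataset, selection=True,
                                            include_cc=include_coalescent_correction)
    stat = 2.0 * (ll_sel - ll_neu)
    if stat < 0:
        if stat < -1e-6:  # pragma: no cover - selection model nests neutral
            logger.warning("negative HKA LRT statistic %.3g clipped to 0", stat)
        stat = 0.0
    df = len(dataset.selected)
    return HKAResult(
        statistic=float(stat), df=df, p_value=float(stats.chi2.sf(stat, df)),
        loglik_neutral=ll_neu, loglik_selection=ll_sel,
        T_neutral=t_neu, T_selection=t_sel,
        theta_neutral=theta_neu, theta_selection=theta_sel, k=k,
    )


def simulate_hka_dataset(
    rng: np.random.Generator,
    theta: np.ndarray,
    L: np.ndarray,
    n: np.ndarray,
    T: float,
    k: dict[int, float] | None = None,
    selected: tuple[int, ...] = (),
    include_coalescent_correction: bool = True,
) -> HKADataset:
    """Draw an HKA dataset from the model itself (for calibration studies)."""
    theta = np.asarray(theta, dtype=float)
    L = np.asarray(L, dtype=float)
    n = np.asarray(n, dtype=int)
    ds = HKADataset(S=np.zeros_like(theta), D=np.zeros_like(theta), L=L, n=n,
                    selected=selected)
    a = ds.a_n()
    c = ds.divergence_coeff(include_coalescent_correction)
    k_vec = np.ones(len(theta))
    for i, val in (k or {}).items():
        k_vec[i] = val
    S = rng.poisson(k_vec * theta * L * a)
    D = rng.poisson(theta * L * (T + c))
    return HKADataset(S=S, D=D, L=L, n=n, selected=selected, locus_ids=ds.locus_ids)


# ---------------------------------------------------------------------------
# recovery evaluation against simulator truth
# ---------------------------------------------------------------------------

def recovery_metrics(truth: dict[str, str], calls: dict[str, str]) -> dict[str, float]:
    """Sensitivity and false-positive rate per planted regime.

    An ``invariant`` call counts as detection of a planted purifying regime
    (complete fixation is the extreme of the diversity-loss signature, and
    the flanking-gene scan reads it as sweep evidence), and likewise as a
    false positive for purifying when the gene was not planted purifying.
    """
    out = {}
    for regime, detect in (("purifying", {"purifying", "invariant"}),
                           ("balancing", {"balancing"})):
        planted = [g for g, r in truth.items() if r == regime]
        others = [g for g, r in truth.items() if r != regime]
        tp = sum(1 for g in planted if calls.get(g) in detect)
        fp = sum(1 for g in others if calls.get(g) in detect)
        out[f"{regime}_sensitivity"] = tp / len(planted) if planted else float("nan")
        out[f"{regime}_fpr"] = fp / len(others) if others else float("nan")
    return out
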