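"""Readers and writers for every on-disk format the pipeline touches.

All parsing is strict and happens here: analysis modules only ever see the
validated in-memory domain objects defined below (haplotype alignments,
population partitions, gene models, pathway maps).  Coordinates are handled
as 0-based half-open internally; GFF3 on disk is 1-based inclusive and is
converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_CHARS = frozenset("ACGTN-")

#: group labels recognised in a population partition
GROUPS = ("landrace", "wild", "outgroup")

# encoding used throughout: A,C,G,T -> 0..3, anything missing (N, -) -> 255
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
_DECODE = np.array(list("ACGT"), dtype="U1")

MISSING = np.uint8(255)


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


class AlignmentError(FormatError):
    """Alignment-specific invariant violation (ragged records, bad symbols)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeAlignment:
    """Aligned haploid CDS sequences for one gene.

    Sequences are uppercase strings over ``{A, C, G, T, N, -}`` and all share
    one length.  ``frame_offset`` is the 0-based position of the first
    complete codon.
    """

    gene_id: str
    sample_ids: list[str]
    sequences: list[str]
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError(
                f"{self.gene_id}: {len(self.sample_ids)} sample ids for "
                f"{len(self.sequences)} sequences"
            )
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise AlignmentError(f"{self.gene_id}: duplicate sample ids")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            for i, s in enumerate(self.sequences):
                if len(s) != len(self.sequences[0]):
                    raise AlignmentError(
                        f"{self.gene_id}: record {self.sample_ids[i]!r} has "
                        f"length {len(s)}, expected {len(self.sequences[0])}"
                    )
        if not self.sequences or len(self.sequences[0]) == 0:
            raise AlignmentError(f"{self.gene_id}: empty alignment")
        for i, s in enumerate(self.sequences):
            bad = set(s) - VALID_CHARS
            if bad:
                raise AlignmentError(
                    f"{self.gene_id}: record {self.sample_ids[i]!r} contains "
                    f"invalid symbols {sorted(bad)}"
                )
        if self.frame_offset not in (0, 1, 2):
            raise AlignmentError(f"frame_offset must be 0, 1 or 2, got {self.frame_offset}")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def encoded(self) -> np.ndarray:
        """(n, L) uint8 matrix; A,C,G,T -> 0..3, N and gaps -> 255."""
        flat = np.frombuffer("".join(self.sequences).encode("ascii"), dtype=np.uint8)
        return _ENCODE[flat].reshape(self.n, self.length)

    def subset(self, sample_ids: Sequence[str]) -> "HaplotypeAlignment":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"{self.gene_id}: samples not in alignment: {missing}")
        return HaplotypeAlignment(
            gene_id=self.gene_id,
            sample_ids=list(sample_ids),
            sequences=[self.sequences[index[s]] for s in sample_ids],
            frame_offset=self.frame_offset,
        )


@dataclass(frozen=True)
class GeneModel:
    """Genomic placement of one gene; used to order genes along chromosomes."""

    gene_id: str
    chromosome: str
    start: int  # 0-based
    end: int    # half-open
    strand: str = "+"
    cds_intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-'")
        prev_end = None
        for s, e in self.cds_intervals:
            if not s < e:
                raise FormatError(f"{self.gene_id}: empty CDS interval ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise FormatError(f"{self.gene_id}: CDS intervals overlap or are unsorted")
            prev_end = e


@dataclass
class PopulationPartition:
    """Mapping sample id -> group label (landrace / wild / outgroup)."""

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        for sample, group in self.assignment.items():
            if group not in GROUPS:
                raise FormatError(
                    f"sample {sample!r}: unknown group {group!r} (expected one of {GROUPS})"
                )

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]

    def group_of(self, sample: str) -> str | None:
        return self.assignment.get(sample)

    def members_in(self, alignment: HaplotypeAlignment, group: str) -> list[str]:
        present = set(alignment.sample_ids)
        return [s for s in self.samples(group) if s in present]


@dataclass
class PathwayMap:
    """gene id -> (pathway name, pathway-position index).

    The position index numbers enzymes (or groups of enzymes between branch
    points) from upstream to downstream within a pathway.
    """

    positions: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        for gene, (pathway, ppi) in self.positions.items():
            if not isinstance(ppi, (int, np.integer)) or isinstance(ppi, bool) or ppi < 1:
                raise FormatError(f"{gene}: pathway position must be a positive integer, got {ppi!r}")

    def pathway(self, gene_id: str) -> str:
        return self.positions[gene_id][0]

    def ppi(self, gene_id: str) -> int:
        return int(self.positions[gene_id][1])

    def genes_in(self, pathway: str) -> list[str]:
        return [g for g, (p, _) in self.positions.items() if p == pathway]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta_alignment(path: str | Path, gene_id: str | None = None) -> HaplotypeAlignment:
    """Read a one-gene multiple alignment from FASTA.

    Record order is preserved; sequences are uppercased.  Ragged record
    lengths raise :class:`AlignmentError` naming the offending record.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    gid = gene_id if gene_id is not None else path.stem
    ids = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    ref_len = len(seqs[0])
    for i, s in enumerate(seqs):
        if len(s) != ref_len:
            raise AlignmentError(
                f"{path}: record {i + 1} ({ids[i]!r}) has length {len(s)}, "
                f"expected {ref_len}"
            )
    return HaplotypeAlignment(gene_id=gid, sample_ids=ids, sequences=seqs)


def write_fasta_alignment(alignment: HaplotypeAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(alignment.sample_ids, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Read (possibly unequal-length) FASTA records, e.g. reference CDS."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise FormatError(f"{path}: no FASTA records")
    return out


def write_fasta_sequences(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def alignment_from_vcf(
    reference_cds: str,
    vcf_path: str | Path,
    region: str,
    partition: PopulationPartition | None = None,
    pseudo_phase_seed: int | None = None,
) -> HaplotypeAlignment:
    """Reconstruct per-haplotype sequences from a reference CDS plus a VCF.

    Biallelic SNP records within ``region`` are substituted into the
    reference; missing genotypes become ``N``.  Indels and multiallelic
    records are skipped with a logged count.  Phased diploid genotypes are
    split into two haplotypes named ``<sample>.1`` / ``<sample>.2``;
    unphased heterozygotes are rejected unless ``pseudo_phase_seed`` is set,
    in which case alleles are assigned at random under that seed (the choice
    is recorded in the log).
    """
    from cyvcf2 import VCF

    reference_cds = reference_cds.upper()
    chrom = region.split(":", 1)[0]
    vcf = VCF(str(vcf_path))
    sample_names = list(vcf.samples)
    rng = np.random.default_rng(pseudo_phase_seed) if pseudo_phase_seed is not None else None

    # first pass over records to learn ploidy from the genotypes
    records = [v for v in vcf(region)] if ":" in region else [
        v for v in vcf if v.CHROM == chrom
    ]
    ploidy = 1
    for v in records:
        if v.genotypes:
            ploidy = max(len(g) - 1 for g in v.genotypes)
            break

    if ploidy == 1:
        hap_ids = list(sample_names)
    else:
        hap_ids = [f"{s}.{k}" for s in sample_names for k in (1, 2)]
    base = np.frombuffer(reference_cds.encode("ascii"), dtype=np.uint8)
    haps = np.tile(base, (len(hap_ids), 1))

    skipped = 0
    for v in records:
        if not v.is_snp or len(v.ALT) != 1:
            skipped += 1
            continue
        pos = v.POS - 1  # VCF is 1-based
        if pos >= len(reference_cds):
            raise FormatError(
                f"{vcf_path}: position {v.POS} outside reference of length {len(reference_cds)}"
            )
        alt = v.ALT[0].upper().encode("ascii")[0]
        for si, g in enumerate(v.genotypes):
            alleles, phased = g[:-1], g[-1]
            if ploidy == 1:
                targets = [(si, alleles[0])]
            else:
                a, b = alleles[0], alleles[1]
                if a != b and not phased and a >= 0 and b >= 0:
                    if rng is None:
                        raise FormatError(
                            f"{vcf_path}: unphased heterozygote for sample "
                            f"{sample_names[si]!r} at {v.CHROM}:{v.POS}; set "
                            f"pseudo_phase_seed to randomise"
                        )
                    if rng.integers(2):
                        a, b = b, a
                        logger.debug("pseudo-phased %s at %s:%d", sample_names[si], v.CHROM, v.POS)
                targets = [(2 * si, a), (2 * si + 1, b)]
            for row, allele in targets:
                if allele < 0:
                    haps[row, pos] = ord("N")
                elif allele == 1:
                    haps[row, pos] = alt
    if skipped:
        logger.info("%s: skipped %d non-biallelic-SNP records in %s", vcf_path, skipped, region)

    seqs = [h.tobytes().decode("ascii") for h in haps]
    return HaplotypeAlignment(gene_id=chrom, sample_ids=hap_ids, sequences=seqs)


def vcf_from_alignment(
    alignment: HaplotypeAlignment,
    reference_cds: str,
    path: str | Path,
    append: bool = False,
    write_header: bool = True,
    contigs: Iterable[tuple[str, int]] | None = None,
) -> int:
    """Write variable sites of an alignment as a haploid VCF v4.2 vs a reference.

    Every haplotype becomes one (haploid) VCF sample.  Returns the number of
    records written.  Sites where the only non-reference state is missing
    data are not emitted (missing genotypes still appear at true variant
    sites as '.').
    """
    reference_cds = reference_cds.upper()
    if len(reference_cds) != alignment.length:
        raise FormatError("reference length does not match alignment length")
    enc = alignment.encoded()
    ref = _ENCODE[np.frombuffer(reference_cds.encode("ascii"), dtype=np.uint8)]
    mode = "a" if append else "w"
    n_written = 0
    with open(path, mode) as fh:
        if write_header:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for name, length in contigs or []:
                fh.write(f"##contig=<ID={name},length={length}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(alignment.sample_ids)
                + "\n"
            )
        for pos in range(alignment.length):
            col = enc[:, pos]
            observed = set(int(c) for c in col if c != MISSING)
            alts = sorted(observed - {int(ref[pos])})
            if not alts:
                continue
            if len(alts) > 1:
                logger.warning(
                    "%s pos %d: %d alternate alleles; writing multiallelic record",
                    alignment.gene_id, pos + 1, len(alts),
                )
            alt_index = {a: k + 1 for k, a in enumerate(alts)}
            gts = []
            for c in col:
                if c == MISSING:
                    gts.append(".")
                elif int(c) == int(ref[pos]):
                    gts.append("0")
                else:
                    gts.append(str(alt_index[int(c)]))
            fh.write(
                f"{alignment.gene_id}\t{pos + 1}\t.\t{_DECODE[ref[pos]]}\t"
                + ",".join(_DECODE[a] for a in alts)
                + "\t.\tPASS\t.\tGT\t"  # QUAL/FILTER/INFO then haploid GTs
                + "\t".join(gts)
                + "\n"
            )
            n_written += 1
    return n_written


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_partition(path: str | Path) -> PopulationPartition:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("sample", "group"), path)
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise FormatError(f"{path}: duplicated sample ids {dups}")
    return PopulationPartition(dict(zip(df["sample"], df["group"])))


def read_pathway_map(path: str | Path) -> PathwayMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("gene", "pathway", "ppi"), path)
    positions: dict[str, tuple[str, int]] = {}
    for _, row in df.iterrows():
        try:
            ppi = int(row["ppi"])
        except (TypeError, ValueError):
            raise FormatError(f"{path}: non-integer pathway position {row['ppi']!r} for {row['gene']!r}")
        if str(ppi) != str(row["ppi"]).strip():
            raise FormatError(f"{path}: non-integer pathway position {row['ppi']!r} for {row['gene']!r}")
        positions[row["gene"]] = (row["pathway"], ppi)
    return PathwayMap(positions)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression table: `gene` column plus one or more FPKM timepoint columns."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("gene",), path)
    value_cols = [c for c in df.columns if c != "gene"]
    if not value_cols:
        raise FormatError(f"{path}: expression table has no FPKM columns")
    return df


def read_tables(
    partition_path: str | Path,
    pathway_path: str | Path,
    expression_path: str | Path | None = None,
) -> tuple[PopulationPartition, PathwayMap, pd.DataFrame | None]:
    partition = read_partition(partition_path)
    pathway = read_pathway_map(pathway_path)
    expression = None
    if expression_path is not None:
        expression = read_expression(expression_path)
        unknown = set(expression["gene"]) - set(pathway.positions)
        if unknown:
            logger.warning(
                "%s: %d expression rows for genes absent from the pathway map (retained)",
                expression_path, len(unknown),
            )
    return partition, pathway, expression


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


# ---------------------------------------------------------------------------
# gene models (GFF3 / BED6)
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene placements from GFF3 (``gene`` + ``CDS`` features) or BED6.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention at this boundary.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _read_bed6(path)
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{line_no}: expected 9 GFF3 columns, got {len(parts)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr_map.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{line_no}: gene feature without ID attribute")
                genes[gid] = {
                    "chrom": chrom,
                    "start": int(start) - 1,
                    "end": int(end),
                    "strand": strand,
                    "cds": [],
                }
            elif ftype == "CDS":
                parent = attr_map.get("Parent") or attr_map.get("ID")
                if parent in genes:
                    genes[parent]["cds"].append((int(start) - 1, int(end)))
    models = []
    for gid, g in genes.items():
        cds = sorted(g["cds"])
        if g["strand"] == "-":
            cds = cds[::-1]  # transcription order, 5' -> 3'
            cds = tuple(sorted(cds))  # stored sorted; orientation carried by strand
        models.append(
            GeneModel(
                gene_id=gid, chromosome=g["chrom"], start=g["start"], end=g["end"],
                strand=g["strand"], cds_intervals=tuple(sorted(g["cds"])),
            )
        )
    models.sort(key=lambda m: (m.chromosome, m.start))
    return models


def _read_bed6(path: Path) -> list[GeneModel]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    models = [
        GeneModel(
            gene_id=row["name"], chromosome=row["chrom"],
            start=int(row["start"]), end=int(row["end"]), strand=row["strand"],
        )
        for _, row in df.iterrows()
    ]
    models.sort(key=lambda m: (m.chromosome, m.start))
    return models


def write_gene_models_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{m.chromosome}\tpathsel\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            for s, e in m.cds_intervals:
                fh.write(
                    f"{m.chromosome}\tpathsel\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\tParent={m.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# gene statistics table
# ---------------------------------------------------------------------------

#: stable column order for per-gene statistics tables
GENE_STATS_COLUMNS = [
    "gene", "group", "n", "L", "L_effective", "S",
    "theta_pi", "theta_w", "tajimas_d", "fst",
    "Ka", "Ks", "ka_ks", "kaks_p_vs_1", "call",
]

INVARIANT = "INVARIANT"


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if np.isnan(value):
            return "NA"
        return f"{value:.10g}"
    return str(value)


def write_gene_stats(records: Sequence[Mapping], path: str | Path) -> None:
    """Write per-gene, per-group statistics as TSV with a stable column order.

    ``tajimas_d`` equal to None is written as the literal marker
    ``INVARIANT`` (never 0.0).  Records are dicts keyed by the names in
    :data:`GENE_STATS_COLUMNS`; absent keys become NA.
    """
    if not records:
        raise FormatError("write_gene_stats: no records")
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_STATS_COLUMNS) + "\n")
        for rec in records:
            row = []
            for col in GENE_STATS_COLUMNS:
                val = rec.get(col)
                if col == "tajimas_d" and val is None and rec.get("S") == 0:
                    row.append(INVARIANT)
                else:
                    row.append(_fmt(val))
            fh.write("\t".join(row) + "\n")


def read_gene_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    return df


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Write a tree (Newick string or an object with ``to_newick()``)."""
    if hasattr(tree, "to_newick"):
        text = tree.to_newick()
    else:
        text = str(tree)
    text = text.strip()
    if not text.endswith(";"):
        text += ";"
    with open(path, "w") as fh:
        fh.write(text + "\n")
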