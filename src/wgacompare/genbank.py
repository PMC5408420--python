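"""GenBank input normalization.

Annotated microbial genomes arrive as GenBank flat files: one record for a
complete genome, several records sharing an organism name for a draft
assembly.  Downstream comparative analysis needs clean, uniform inputs, so
this module validates the records, applies a small set of deterministic
corrections (over-long accessions, malformed locus identifiers), strips
pseudogenes, merges records per organism, and exports a multi-FASTA sequence
set plus a tab-delimited annotation map that together fully determine every
later stage.

Coordinates are GenBank-style 1-based inclusive throughout this module and
in the annotation map; conversion to 0-based half-open happens only where
alignment columns or BED-like tracks are involved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

MAX_ACCESSION_LEN = 16
_LOCUS_OK = re.compile(r"^[A-Za-z0-9_.\-]+$")
_LOCUS_BAD_CHAR = re.compile(r"[^A-Za-z0-9_.\-]")

ANNOTATION_COLUMNS = [
    "organism",
    "contig",
    "locus",
    "start",
    "end",
    "strand",
    "product",
]


@dataclass(frozen=True)
class ContigSequence:
    """One contig: normalized accession (<=16 chars) plus uppercase sequence."""

    accession: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature as a single interval, 1-based inclusive."""

    locus_id: str
    contig_accession: str
    start: int
    end: int
    strand: str  # "+" or "-"
    product: str = ""
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"CDS {self.locus_id}: invalid interval [{self.start},{self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"CDS {self.locus_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """One input genome: ordered contigs and CDS features for one organism."""

    organism_name: str
    contigs: list[ContigSequence]
    cds_features: list[CdsFeature]

    @property
    def is_draft(self) -> bool:
        return len(self.contigs) > 1

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)

    def contig(self, accession: str) -> ContigSequence:
        for c in self.contigs:
            if c.accession == accession:
                return c
        raise KeyError(f"{self.organism_name}: no contig {accession!r}")

    def validate(self) -> None:
        if not self.organism_name:
            raise ValueError("genome has empty organism name")
        accs = [c.accession for c in self.contigs]
        if len(set(accs)) != len(accs):
            raise ValueError(f"{self.organism_name}: duplicate contig accessions")
        lengths = {c.accession: c.length for c in self.contigs}
        for cds in self.cds_features:
            if cds.contig_accession not in lengths:
                raise ValueError(
                    f"{self.organism_name}: CDS {cds.locus_id} references "
                    f"unknown contig {cds.contig_accession}"
                )
            if cds.end > lengths[cds.contig_accession]:
                raise ValueError(
                    f"{self.organism_name}: CDS {cds.locus_id} end {cds.end} "
                    f"exceeds contig length {lengths[cds.contig_accession]}"
                )


@dataclass
class CorrectionLog:
    """Audit trail of every automatic correction, one entry per change."""

    entries: list[tuple[str, str, str, str]] = field(default_factory=list)
    # (record identifier, rule, before, after)

    def add(self, record: str, rule: str, before: str, after: str) -> None:
        self.entries.append((record, rule, before, after))

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("record\trule\tbefore\tafter\n")
            for row in self.entries:
                fh.write("\t".join(row) + "\n")

    def __len__(self) -> int:
        return len(self.entries)


def _collapse_ws(name: str) -> str:
    return " ".join(name.split())


def _feature_interval(feature) -> tuple[int, int, str]:
    """Minimal/maximal 1-based coordinates and strand of a (possibly compound)
    Biopython feature location."""
    loc = feature.location
    start = int(loc.start) + 1  # biopython is 0-based half-open
    end = int(loc.end)
    strand = "-" if loc.strand == -1 else "+"
    return start, end, strand


def read_genbank(paths: Iterable[str | Path]) -> list[SeqRecord]:
    """Parse one or more GenBank flat files (dirs are scanned for .gb/.gbk/.gbff)."""
    records: list[SeqRecord] = []
    for p in paths:
        p = Path(p)
        if p.is_dir():
            files = sorted(
                f for f in p.iterdir() if f.suffix in (".gb", ".gbk", ".gbff")
            )
        else:
            files = [p]
        for f in files:
            for rec in SeqIO.parse(str(f), "genbank"):
                rec.annotations.setdefault("source_file", str(f))
                records.append(rec)
    return records


def _shorten_accession(acc: str, taken: set[str]) -> str:
    """Truncate to 14 chars + 2-char base-36 disambiguator, preserving uniqueness."""
    base = acc[: MAX_ACCESSION_LEN - 2]
    digits = "0123456789abcdefghijklmnopqrstuvwxyz"
    for i in range(36 * 36):
        cand = base + digits[i // 36] + digits[i % 36]
        if cand not in taken:
            return cand
    raise ValueError(f"cannot disambiguate accession {acc!r}")


def _normalize_locus(locus: str, taken: set[str], log: CorrectionLog, rec_id: str) -> str:
    fixed = _LOCUS_BAD_CHAR.sub("_", locus) if locus else "_"
    if fixed != locus:
        log.add(rec_id, "locus_id_normalized", locus, fixed)
    if fixed in taken:
        n = 2
        while f"{fixed}_{n}" in taken:
            n += 1
        log.add(rec_id, "locus_id_deduplicated", fixed, f"{fixed}_{n}")
        fixed = f"{fixed}_{n}"
    return fixed


def validate_and_correct(
    records: Sequence[SeqRecord],
) -> tuple[list[GenomeRecord], CorrectionLog]:
    """Validate raw GenBank records and apply automatic corrections.

    Each input record becomes a single-contig :class:`GenomeRecord` candidate
    (use :func:`group_by_organism` afterwards to merge drafts).  Corrections:

    * accessions longer than 16 characters are shortened deterministically;
    * locus identifiers are restricted to ``[A-Za-z0-9_.-]`` with collision
      suffixes;
    * pseudogene features are removed.

    Uncorrectable problems (empty sequence, CDS extending past the contig
    end) raise ``ValueError`` naming the offending record.
    """
    log = CorrectionLog()
    out: list[GenomeRecord] = []
    taken_acc: set[str] = set()
    # locus uniqueness is per organism
    taken_locus: dict[str, set[str]] = {}

    for rec in records:
        rec_id = rec.annotations.get("source_file", rec.id)
        organism = _collapse_ws(
            rec.annotations.get("organism") or rec.annotations.get("source") or ""
        )
        if not organism:
            raise ValueError(f"{rec_id}: record has no organism name")
        seq = str(rec.seq).upper()
        if not seq or set(seq) == {"N"}:
            raise ValueError(f"{rec_id}: record has an empty sequence")

        acc = rec.id or rec.name
        if not acc or acc.isspace():
            raise ValueError(f"{rec_id}: record has no accession")
        acc = acc.strip()
        if len(acc) > MAX_ACCESSION_LEN:
            short = _shorten_accession(acc, taken_acc)
            log.add(rec_id, "accession_shortened", acc, short)
            acc = short
        taken_acc.add(acc)

        loci = taken_locus.setdefault(organism, set())
        cds: list[CdsFeature] = []
        counter = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            counter += 1
            quals = feat.qualifiers
            if "pseudo" in quals or "pseudogene" in quals:
                name = quals.get("locus_tag", [f"CDS_{counter}"])[0]
                log.add(rec_id, "pseudogene_removed", name, "")
                continue
            locus_raw = quals.get("locus_tag", quals.get("gene", [f"{acc}_cds{counter}"]))[0]
            locus = _normalize_locus(locus_raw, loci, log, rec_id)
            loci.add(locus)
            start, end, strand = _feature_interval(feat)
            if end > len(seq):
                raise ValueError(
                    f"{rec_id}: CDS {locus} end {end} exceeds contig length {len(seq)}"
                )
            product = quals.get("product", [""])[0]
            cds.append(
                CdsFeature(
                    locus_id=locus,
                    contig_accession=acc,
                    start=start,
                    end=end,
                    strand=strand,
                    product=product,
                )
            )

        genome = GenomeRecord(
            organism_name=organism,
            contigs=[ContigSequence(accession=acc, sequence=seq)],
            cds_features=cds,
        )
        genome.validate()
        out.append(genome)
    return out, log


def group_by_organism(candidates: Sequence[GenomeRecord]) -> list[GenomeRecord]:
    """Merge records sharing an organism name into one genome (draft assembly).

    Contigs are concatenated in input order; a contig accession reused across
    merged records is a hard error.
    """
    merged: dict[str, GenomeRecord] = {}
    order: list[str] = []
    for cand in candidates:
        name = _collapse_ws(cand.organism_name)
        if name not in merged:
            merged[name] = GenomeRecord(name, [], [])
            order.append(name)
        g = merged[name]
        existing = {c.accession for c in g.contigs}
        for c in cand.contigs:
            if c.accession in existing:
                raise ValueError(
                    f"{name}: duplicate contig accession {c.accession!r} across records"
                )
        g.contigs.extend(cand.contigs)
        g.cds_features.extend(cand.cds_features)
    out = [merged[n] for n in order]
    for g in out:
        g.validate()
    return out


def write_multifasta(genome: GenomeRecord, path: str | Path) -> None:
    """One uppercase FASTA entry per contig, header = accession, 60-col wrap."""
    genome.validate()
    with open(path, "w") as fh:
        for c in genome.contigs:
            fh.write(f">{c.accession}\n")
            seq = c.sequence.upper()
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def build_annotation_map(genomes: Sequence[GenomeRecord]) -> pd.DataFrame:
    """Tab-delimited gene-call table driving ortholog clustering and SNP
    annotation: one row per retained CDS, sorted by (genome order, contig,
    start) so output is byte-deterministic."""
    rows = []
    for g in genomes:
        contig_order = {c.accession: i for i, c in enumerate(g.contigs)}
        for cds in sorted(
            g.cds_features,
            key=lambda f: (contig_order[f.contig_accession], f.start, f.locus_id),
        ):
            rows.append(
                (
                    g.organism_name,
                    cds.contig_accession,
                    cds.locus_id,
                    cds.start,
                    cds.end,
                    cds.strand,
                    cds.product,
                )
            )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotation_map(amap: pd.DataFrame, path: str | Path) -> None:
    amap.to_csv(path, sep="\t", index=False)


def read_annotation_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"product": str}, keep_default_na=False)
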