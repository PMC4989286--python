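"""Cross-species miRNA annotation harmonization.

Mature miRNA catalogues differ widely in completeness between species, so a
sparsely annotated target genome can borrow annotation from better-studied
relatives.  The harmonization proceeds in four sequential steps:

1. load mature miRNA sequence sets for each species and normalize them
   (uppercase DNA alphabet, U->T);
2. consolidate the sets by collapsing sequences that are identical across
   species into a single record carrying multi-species provenance;
3. place every consolidated sequence on the target genome requiring a
   perfect (zero-mismatch) match on either strand, discarding promiscuous
   sequences that hit more than ``max_locations`` genomic positions;
4. merge hits that land at (approximately) the same genomic location into
   unified miRNA loci.

The output is an :class:`AnnotationSet` of strand-aware, non-overlapping
loci plus a "funnel" report with the record count surviving each step.

Coordinates are 0-based half-open internally and in BED output; GFF3 output
uses the standard 1-based inclusive convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import DataError, ParseError, ValidationError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: nucleotide-length bounds for a plausible mature miRNA
MIN_MATURE_LEN = 15
MAX_MATURE_LEN = 30


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatureSequence:
    """A normalized mature miRNA sequence from one species catalogue."""

    name: str
    species: str
    sequence: str


@dataclass(frozen=True)
class ConsolidatedSequence:
    """One distinct sequence string with the (name, species) pairs carrying it."""

    sequence: str
    members: frozenset[tuple[str, str]]  # (name, species)
    representative_name: str

    @property
    def species(self) -> frozenset[str]:
        return frozenset(sp for _, sp in self.members)


@dataclass(frozen=True)
class GenomeHit:
    """A perfect-match placement of a consolidated sequence on the genome.

    ``sequence_ref`` is the consolidated sequence string itself (unique key).
    """

    sequence_ref: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class MiRNALocus:
    chrom: str
    start: int
    end: int
    strand: str
    name: str
    species_provenance: frozenset[str]
    member_sequences: frozenset[str]


@dataclass
class AnnotationSet:
    loci: list[MiRNALocus]
    genome_id: str = ""
    parameters: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.loci)

    def by_name(self) -> dict[str, MiRNALocus]:
        return {loc.name: loc for loc in self.loci}


@dataclass
class AlignmentReport:
    """Which consolidated sequences were excluded or failed to place."""

    excluded_multi: dict[str, int] = field(default_factory=dict)  # seq -> n hits
    unaligned: list[str] = field(default_factory=list)
    n_aligned: int = 0


@dataclass
class HarmonizerConfig:
    species_fastas: dict[str, str | Path]
    genome_fasta: str | Path
    target_species: str = "cfa"
    max_locations: int = 10
    gap_tolerance: int = 0
    genome_id: str = "genome"

    @property
    def precedence(self) -> list[str]:
        order = [self.target_species]
        order += [sp for sp in self.species_fastas if sp != self.target_species]
        return order


# ---------------------------------------------------------------------------
# step 1: load and normalize mature sequence sets
# ---------------------------------------------------------------------------

def normalize_sequence(raw: str, record_name: str = "?") -> str:
    """Uppercase, RNA->DNA (U->T); reject non-ACGTU characters and odd lengths."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValidationError(
            f"record {record_name!r}: non-ACGTU characters {sorted(bad)}"
        )
    if not (MIN_MATURE_LEN <= len(seq) <= MAX_MATURE_LEN):
        raise ValidationError(
            f"record {record_name!r}: mature length {len(seq)} outside "
            f"[{MIN_MATURE_LEN}, {MAX_MATURE_LEN}]"
        )
    return seq


def load_mature_fasta(path: str | Path, species: str) -> list[MatureSequence]:
    """Read one species' mature miRNA FASTA.

    miRBase-style headers are accepted; only the first whitespace-delimited
    token of the header is used as the name.  Duplicate names within a file
    are an error.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    n_lines = sum(1 for line in path.open() if line.strip())
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed FASTA ({exc})") from exc
    for rec in parsed:
        if not rec.id:
            raise ParseError(f"{path}: FASTA record with empty id")
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate record name {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: record {rec.id!r} has empty sequence")
        records.append(
            MatureSequence(rec.id, species, normalize_sequence(str(rec.seq), rec.id))
        )
    if not records and n_lines > 0:
        raise ParseError(f"{path}: no FASTA records parsed from non-empty file")
    return records


# ---------------------------------------------------------------------------
# step 2: consolidate across species
# ---------------------------------------------------------------------------

def _species_rank(species: str, precedence: Sequence[str] | None) -> int:
    if precedence is None:
        return 0
    try:
        return precedence.index(species)
    except ValueError:
        return len(precedence)


def consolidate_sequences(
    sets: Mapping[str, Iterable[MatureSequence]],
    precedence: Sequence[str] | None = None,
) -> list[ConsolidatedSequence]:
    """Collapse identical sequences across species into single records.

    The representative name is the member name from the highest-precedence
    species (default precedence: input order of ``sets``), ties broken
    lexicographically.  Output is sorted by sequence string so the result is
    independent of input ordering.
    """
    if not sets:
        raise DataError("consolidate_sequences: need at least one species set")
    if precedence is None:
        precedence = list(sets)
    by_seq: dict[str, set[tuple[str, str]]] = {}
    for species, seqs in sets.items():
        pair_seen: set[tuple[str, str]] = set()
        for ms in seqs:
            key = (ms.name, ms.species)
            if key in pair_seen:
                raise ValidationError(f"duplicate (name, species) pair {key}")
            pair_seen.add(key)
            by_seq.setdefault(ms.sequence, set()).add(key)
    out = []
    for seq in sorted(by_seq):
        members = by_seq[seq]
        rep = min(members, key=lambda m: (_species_rank(m[1], precedence), m[0]))[0]
        out.append(ConsolidatedSequence(seq, frozenset(members), rep))
    return out


# ---------------------------------------------------------------------------
# step 3: zero-mismatch genome placement
# ---------------------------------------------------------------------------

def load_genome_fasta(path: str | Path) -> dict[str, str]:
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ParseError(f"{path}: no genome contigs parsed")
    return genome


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def align_exact(
    seqs: Iterable[ConsolidatedSequence],
    genome: Mapping[str, str] | str | Path,
    max_locations: int = 10,
) -> tuple[list[GenomeHit], AlignmentReport]:
    """Place each consolidated sequence on the genome with zero mismatches.

    Both strands are scanned; a minus-strand hit is a genome substring equal
    to the reverse complement of the sequence.  ``N`` in the genome never
    matches.  A sequence with more than ``max_locations`` total placements
    (summed over both strands; an identical +/- placement of a palindromic
    sequence counts as two) is excluded entirely and reported with its hit
    count; zero-hit sequences are reported as unaligned.
    """
    if not isinstance(genome, Mapping):
        genome = load_genome_fasta(genome)
    hits: list[GenomeHit] = []
    report = AlignmentReport()
    for cs in seqs:
        seq_hits: list[GenomeHit] = []
        rc = reverse_complement(cs.sequence)
        for chrom in sorted(genome):
            contig = genome[chrom]
            for pos in _find_all(contig, cs.sequence):
                seq_hits.append(
                    GenomeHit(cs.sequence, chrom, pos, pos + len(cs.sequence), "+")
                )
            for pos in _find_all(contig, rc):
                seq_hits.append(
                    GenomeHit(cs.sequence, chrom, pos, pos + len(cs.sequence), "-")
                )
        if not seq_hits:
            report.unaligned.append(cs.sequence)
        elif len(seq_hits) > max_locations:
            report.excluded_multi[cs.sequence] = len(seq_hits)
        else:
            hits.extend(seq_hits)
            report.n_aligned += 1
    return hits, report


# ---------------------------------------------------------------------------
# step 4: merge co-located hits into loci
# ---------------------------------------------------------------------------

def _clusters(
    hits: Sequence[GenomeHit], gap_tolerance: int
) -> list[list[GenomeHit]]:
    """Single-linkage clustering of hits per (chrom, strand).

    Two hits join when ``next.start < current_end + gap_tolerance``; with the
    default tolerance 0 only genuinely overlapping hits merge (touching
    intervals stay separate).
    """
    groups: dict[tuple[str, str], list[GenomeHit]] = {}
    for h in hits:
        groups.setdefault((h.chrom, h.strand), []).append(h)
    clusters: list[list[GenomeHit]] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda h: (h.start, h.end, h.sequence_ref))
        current = [members[0]]
        cur_end = members[0].end
        for h in members[1:]:
            if h.start < cur_end + gap_tolerance:
                current.append(h)
                cur_end = max(cur_end, h.end)
            else:
                clusters.append(current)
                current = [h]
                cur_end = h.end
        clusters.append(current)
    return clusters


def merge_loci(
    hits: Iterable[GenomeHit],
    consolidated: Mapping[str, ConsolidatedSequence],
    gap_tolerance: int = 0,
    precedence: Sequence[str] | None = None,
    genome_id: str = "genome",
) -> AnnotationSet:
    """Merge co-located hits into strand-aware loci spanning the cluster union.

    The locus name is the representative name of the member sequence whose
    provenance ranks highest in ``precedence``; when several loci end up with
    the same name they are disambiguated with ``-locN`` suffixes in genomic
    order.
    """
    hits = list(hits)
    for h in hits:
        cs = consolidated.get(h.sequence_ref)
        if cs is None:
            raise DataError(f"hit references unknown sequence {h.sequence_ref!r}")
        if h.end - h.start != len(cs.sequence):
            raise ValidationError(f"hit span does not match sequence length: {h}")
    loci: list[MiRNALocus] = []
    for cluster in _clusters(hits, gap_tolerance):
        members = sorted({h.sequence_ref for h in cluster})
        css = [consolidated[s] for s in members]

        def best_rank(cs: ConsolidatedSequence) -> tuple[int, str]:
            rank = min(_species_rank(sp, precedence) for sp in cs.species)
            return rank, cs.representative_name

        name = min(css, key=best_rank).representative_name
        loci.append(
            MiRNALocus(
                chrom=cluster[0].chrom,
                start=min(h.start for h in cluster),
                end=max(h.end for h in cluster),
                strand=cluster[0].strand,
                name=name,
                species_provenance=frozenset().union(*(cs.species for cs in css)),
                member_sequences=frozenset(members),
            )
        )
    loci.sort(key=lambda l: (l.chrom, l.start, l.strand))
    # disambiguate name collisions deterministically in genomic order
    counts: dict[str, int] = {}
    for loc in loci:
        counts[loc.name] = counts.get(loc.name, 0) + 1
    seen: dict[str, int] = {}
    renamed: list[MiRNALocus] = []
    for loc in loci:
        if counts[loc.name] > 1:
            seen[loc.name] = seen.get(loc.name, 0) + 1
            loc = MiRNALocus(
                loc.chrom, loc.start, loc.end, loc.strand,
                f"{loc.name}-loc{seen[loc.name]}",
                loc.species_provenance, loc.member_sequences,
            )
        renamed.append(loc)
    return AnnotationSet(
        renamed, genome_id=genome_id, parameters={"gap_tolerance": gap_tolerance}
    )


# ---------------------------------------------------------------------------
# composition + funnel report
# ---------------------------------------------------------------------------

def build_annotation(config: HarmonizerConfig) -> tuple[AnnotationSet, dict]:
    """Run the four harmonization steps and return (annotation, funnel).

    The funnel reports the record count surviving each step:
    ``n_input_sequences`` (all catalogue records), ``n_consolidated``
    (distinct sequences), ``n_aligned`` (sequences placed with <=
    max_locations hits), ``n_excluded_multi``, ``n_unaligned``, ``n_loci``.
    """
    sets = {
        sp: load_mature_fasta(path, sp)
        for sp, path in config.species_fastas.items()
    }
    n_input = sum(len(v) for v in sets.values())
    consolidated = consolidate_sequences(sets, precedence=config.precedence)
    genome = load_genome_fasta(config.genome_fasta)
    hits, rep = align_exact(consolidated, genome, config.max_locations)
    annotation = merge_loci(
        hits,
        {cs.sequence: cs for cs in consolidated},
        gap_tolerance=config.gap_tolerance,
        precedence=config.precedence,
        genome_id=config.genome_id,
    )
    annotation.parameters.update(
        max_locations=config.max_locations,
        target_species=config.target_species,
    )
    funnel = {
        "n_input_sequences": n_input,
        "n_consolidated": len(consolidated),
        "n_aligned": rep.n_aligned,
        "n_excluded_multi": len(rep.excluded_multi),
        "n_unaligned": len(rep.unaligned),
        "n_loci": len(annotation),
    }
    return annotation, funnel


# ---------------------------------------------------------------------------
# annotation I/O (BED6 / GFF3 / funnel TSV)
# ---------------------------------------------------------------------------

def write_bed(annotation: AnnotationSet, path: str | Path) -> None:
    """BED6, 0-based half-open."""
    with Path(path).open("w") as fh:
        for loc in annotation.loci:
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.name}\t0\t{loc.strand}\n"
            )


def write_gff3(annotation: AnnotationSet, path: str | Path) -> None:
    """GFF3, 1-based inclusive, type ``miRNA``."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for loc in annotation.loci:
            attrs = (
                f"Name={loc.name};"
                f"species_provenance={','.join(sorted(loc.species_provenance))};"
                f"members={','.join(sorted(loc.member_sequences))}"
            )
            fh.write(
                f"{loc.chrom}\tmiratlas\tmiRNA\t{loc.start + 1}\t{loc.end}\t.\t"
                f"{loc.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> AnnotationSet:
    loci = []
    for line in Path(path).open():
        if line.startswith("#") or not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise ParseError(f"{path}: expected 9 GFF3 columns, got {len(fields)}")
        chrom, _src, ftype, start1, end1, _score, strand, _phase, attrs = fields
        if ftype != "miRNA":
            continue
        adict = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        loci.append(
            MiRNALocus(
                chrom=chrom,
                start=int(start1) - 1,
                end=int(end1),
                strand=strand,
                name=adict.get("Name", "?"),
                species_provenance=frozenset(
                    s for s in adict.get("species_provenance", "").split(",") if s
                ),
                member_sequences=frozenset(
                    s for s in adict.get("members", "").split(",") if s
                ),
            )
        )
    return AnnotationSet(loci)


def write_funnel(funnel: Mapping[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("step\tcount\n")
        for key, val in funnel.items():
            fh.write(f"{key}\t{val}\n")


def write_manifest(config: HarmonizerConfig, funnel: Mapping[str, int],
                   path: str | Path) -> None:
    payload = {
        "species_fastas": {k: str(v) for k, v in config.species_fastas.items()},
        "genome_fasta": str(config.genome_fasta),
        "target_species": config.target_species,
        "max_locations": config.max_locations,
        "gap_tolerance": config.gap_tolerance,
        "funnel": dict(funnel),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
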