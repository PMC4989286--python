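"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the data shape of a multi-tissue small-RNA atlas
study: a toy genome with planted miRNA loci, three species' mature-sequence
catalogues with partial conservation (plus an optional promiscuous sequence
planted >10 times to exercise the multi-mapper filter), per-sample read
alignments, a 16-tissue x 5-replicate negative-binomial count matrix with
planted tissue enrichment, qPCR Ct plates linear in -log2 expression with
censoring, and a repeat-dose injury study in which a latent injury level
drives both liver-miRNA serum elevation and ALT/AST.

Every generator is deterministic given (seed, config): each draws from its
own seeded stream, so outputs are bit-reproducible and independent of call
order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import MatureSequence, MiRNALocus, reverse_complement
from .errors import ConfigError
from .quantify import SampleTable

TISSUES_16 = (
    "liver", "brain", "heart", "muscle", "kidney", "lung", "pancreas",
    "testis", "spleen", "thymus", "duodenum", "jejunum", "ileum", "colon",
    "bone_marrow", "plasma",
)

# per-stage stream labels so generators are independent of call order
_STREAM = {"genome": 1, "counts": 2, "reads": 3, "qpcr": 4, "panel": 5}


@dataclass
class SimulationConfig:
    seed: int = 17
    # genome / annotation
    n_chrom: int = 3
    chrom_length: int = 60_000
    n_loci: int = 300
    locus_length: tuple[int, int] = (18, 25)
    species: tuple[str, ...] = ("cfa", "rno", "hsa")
    conservation_all: float = 0.5  # fraction of loci carried by all species
    plant_multimapper: bool = True
    multimapper_copies: int = 11
    # expression design
    tissues: tuple[str, ...] = TISSUES_16
    replicates: int = 5
    baseline_log2_mean: float = 8.0   # log2 RPM of typical loci (~256 RPM)
    baseline_log2_sd: float = 2.0
    hte_baseline_log2_mean: float = 2.5  # off-tissue RPM of planted HTE loci
    hte_baseline_log2_sd: float = 0.4
    dispersion: float = 0.1           # NB: Var = mu + dispersion * mu^2
    te_fold: float = 10.0
    hte_fold: float = 50.0
    n_te: int = 30
    n_hte: int = 20
    n_reference: int = 3
    reference_rpm: float = 5000.0
    depth: int = 1_000_000            # counts per sample
    # read-level simulation
    alignment_depth: int = 20_000
    decoy_fraction: float = 0.1
    read_overlap_guarantee: float = 0.85
    mapped_fraction: float = 0.85
    # qPCR
    qpcr_intercept: float = 36.0
    qpcr_slope: float = 1.0
    qpcr_sigma: float = 0.15
    qpcr_ceiling: float = 40.0        # instrument max, above the 38 cutoff
    qpcr_replicates: int = 3
    # POC panel study
    n_injured: int = 2
    n_control: int = 4
    panel_days: tuple[int, ...] = (1, 7, 14)
    injury_trajectory: tuple[float, ...] = (0.0, 0.3, 0.6, 1.0, 1.5, 2.0)
    liver_targets: tuple[str, ...] = ("cfa-miR-122", "cfa-miR-885")
    nonliver_targets: tuple[str, ...] = ("cfa-miR-1", "cfa-miR-133a", "cfa-miR-216a")
    reference_targets: tuple[str, ...] = ("cfa-miR-16", "cfa-miR-29a", "cfa-miR-186")
    alt_base: float = 30.0
    alt_gain: float = 60.0
    alt_sigma: float = 3.0
    ast_base: float = 35.0
    ast_gain: float = 90.0
    ast_sigma: float = 4.0
    liver_ct_base: float = 32.0
    nonliver_ct_base: float = 35.0
    reference_ct_base: float = 28.0
    injury_ct_gain: float = 2.5       # Ct cycles dropped per unit injury
    panel_sigma: float = 0.2

    def validate(self) -> None:
        if self.n_loci <= 0 or self.depth <= 0 or self.replicates < 2:
            raise ConfigError("n_loci, depth must be positive; replicates >= 2")
        if not (0 <= self.conservation_all <= 1):
            raise ConfigError("conservation_all must be in [0, 1]")
        if not (0 <= self.decoy_fraction <= 1):
            raise ConfigError("decoy_fraction must be in [0, 1]")
        if self.n_te + self.n_hte + self.n_reference > self.n_loci:
            raise ConfigError("planted loci exceed n_loci")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")

    def _rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAM[stage]])


@dataclass
class PlantedTruth:
    """Ground truth of one simulation: what was planted where."""

    loci: list[MiRNALocus]
    species_membership: dict[str, list[str]]          # locus name -> species
    enrichment: dict[str, dict]                       # name -> tissue/fold/class
    baseline_expression: dict[str, float]             # name -> mean RPM
    reference_loci: list[str] = field(default_factory=list)
    multimapper_name: str | None = None
    multimapper_sequence: str | None = None
    injury_profile: dict[str, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "loci": [
                {
                    "chrom": l.chrom, "start": l.start, "end": l.end,
                    "strand": l.strand, "name": l.name,
                    "species_provenance": sorted(l.species_provenance),
                    "member_sequences": sorted(l.member_sequences),
                }
                for l in self.loci
            ],
            "species_membership": self.species_membership,
            "enrichment": self.enrichment,
            "baseline_expression": self.baseline_expression,
            "reference_loci": self.reference_loci,
            "multimapper_name": self.multimapper_name,
            "multimapper_sequence": self.multimapper_sequence,
            "injury_profile": self.injury_profile,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedTruth":
        loci = [
            MiRNALocus(
                e["chrom"], e["start"], e["end"], e["strand"], e["name"],
                frozenset(e["species_provenance"]),
                frozenset(e["member_sequences"]),
            )
            for e in d["loci"]
        ]
        return cls(
            loci, d["species_membership"], d["enrichment"],
            d["baseline_expression"], d.get("reference_loci", []),
            d.get("multimapper_name"), d.get("multimapper_sequence"),
            d.get("injury_profile", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "PlantedTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# genome, species catalogues, planted annotation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def _occurrences(genome: dict[str, str], seq: str) -> int:
    rc = reverse_complement(seq)
    total = 0
    for contig in genome.values():
        total += contig.count(seq) + contig.count(rc)
    return total


def gen_genome_and_annotation(
    cfg: SimulationConfig,
) -> tuple[dict[str, str], PlantedTruth, dict[str, list[MatureSequence]]]:
    """Toy genome with planted loci plus per-species mature catalogues.

    Locus sequences are embedded verbatim (reverse complement on the minus
    strand) at non-overlapping positions and verified to occur exactly once
    genome-wide; the optional multi-mapper sequence is planted
    ``multimapper_copies`` times.  Species membership per locus: with
    probability ``conservation_all`` all species carry the sequence,
    otherwise exactly one (uniformly chosen) does.
    """
    cfg.validate()
    rng = cfg._rng("genome")
    lmin, lmax = cfg.locus_length
    slot = lmax + 40
    per_chrom = cfg.chrom_length // slot
    total_slots = per_chrom * cfg.n_chrom
    n_extra = cfg.multimapper_copies if cfg.plant_multimapper else 0
    if cfg.n_loci + n_extra > total_slots:
        raise ConfigError(
            f"cannot place {cfg.n_loci + n_extra} loci in {total_slots} slots; "
            "increase chrom_length or n_chrom"
        )

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    contigs = {
        c: list(_random_seq(rng, cfg.chrom_length)) for c in chrom_names
    }
    chosen = rng.choice(total_slots, size=cfg.n_loci + n_extra, replace=False)
    chosen.sort()

    def slot_pos(k: int) -> tuple[str, int]:
        return chrom_names[k // per_chrom], (k % per_chrom) * slot + 10

    # draw distinct locus sequences
    sequences: list[str] = []
    seen: set[str] = set()
    while len(sequences) < cfg.n_loci + 1:  # +1 for the multi-mapper
        s = _random_seq(rng, int(rng.integers(lmin, lmax + 1)))
        if s in seen or reverse_complement(s) in seen:
            continue
        seen.add(s)
        sequences.append(s)
    multi_seq = sequences.pop()

    placements: list[tuple[str, int, int, str, str]] = []  # chrom,s,e,strand,seq
    for i in range(cfg.n_loci):
        chrom, pos = slot_pos(int(chosen[i]))
        strand = "+" if rng.random() < 0.5 else "-"
        placements.append((chrom, pos, pos + len(sequences[i]), strand, sequences[i]))
    multi_slots = [int(chosen[cfg.n_loci + j]) for j in range(n_extra)]
    for k in multi_slots:
        chrom, pos = slot_pos(k)
        placements.append((chrom, pos, pos + len(multi_seq), "+", multi_seq))

    for chrom, s, e, strand, seq in placements:
        written = seq if strand == "+" else reverse_complement(seq)
        contigs[chrom][s:e] = list(written)
    genome = {c: "".join(v) for c, v in contigs.items()}

    # verify uniqueness; redraw colliding background-induced duplicates
    for i in range(cfg.n_loci):
        attempts = 0
        while _occurrences(genome, sequences[i]) != 1:
            attempts += 1
            if attempts > 50:
                raise ConfigError("could not place a unique locus sequence")
            new = _random_seq(rng, len(sequences[i]))
            chrom, s, e, strand, _ = placements[i]
            placements[i] = (chrom, s, e, strand, new)
            sequences[i] = new
            contig = list(genome[chrom])
            contig[s:e] = list(new if strand == "+" else reverse_complement(new))
            genome[chrom] = "".join(contig)

    # species membership + names (target species listed first in cfg.species)
    species_sets: dict[str, list[MatureSequence]] = {sp: [] for sp in cfg.species}
    membership: dict[str, list[str]] = {}
    loci: list[MiRNALocus] = []
    for i, (chrom, s, e, strand, seq) in enumerate(placements[: cfg.n_loci]):
        base = f"miR-{i + 1:04d}"
        if rng.random() < cfg.conservation_all:
            carriers = list(cfg.species)
        else:
            carriers = [cfg.species[int(rng.integers(len(cfg.species)))]]
        rep_species = next(sp for sp in cfg.species if sp in carriers)
        name = f"{rep_species}-{base}"
        for sp in carriers:
            species_sets[sp].append(MatureSequence(f"{sp}-{base}", sp, seq))
        membership[name] = carriers
        loci.append(
            MiRNALocus(chrom, s, e, strand, name, frozenset(carriers),
                       frozenset([seq]))
        )
    multi_name = None
    if cfg.plant_multimapper:
        multi_name = f"{cfg.species[0]}-miR-multi"
        for sp in cfg.species:
            species_sets[sp].append(MatureSequence(f"{sp}-miR-multi", sp, multi_seq))

    # planted expression design
    names = [l.name for l in loci]
    roles = rng.permutation(cfg.n_loci)
    ref_idx = roles[: cfg.n_reference]
    hte_idx = roles[cfg.n_reference: cfg.n_reference + cfg.n_hte]
    te_idx = roles[cfg.n_reference + cfg.n_hte:
                   cfg.n_reference + cfg.n_hte + cfg.n_te]
    # baselines are true RPM: HTE loci get a fixed low off-tissue abundance
    # and references a fixed high one, then the remaining loci are scaled to
    # fill the rest of the million-read budget so realized RPM ~ baseline
    baseline = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd,
                                 cfg.n_loci)
    baseline[hte_idx] = 2.0 ** rng.normal(
        cfg.hte_baseline_log2_mean, cfg.hte_baseline_log2_sd, cfg.n_hte
    )
    baseline[ref_idx] = cfg.reference_rpm * 2.0 ** rng.normal(
        0.0, 0.05, cfg.n_reference
    )
    special = np.zeros(cfg.n_loci, dtype=bool)
    special[hte_idx] = True
    special[ref_idx] = True
    budget = 1e6 - baseline[special].sum()
    if budget > 0 and baseline[~special].sum() > 0:
        baseline[~special] *= budget / baseline[~special].sum()
    enrichment: dict[str, dict] = {}
    tissue_pool = list(cfg.tissues)
    for j, idx in enumerate(hte_idx):
        enrichment[names[idx]] = {
            "tissue": tissue_pool[j % len(tissue_pool)],
            "fold": cfg.hte_fold,
            "class": "HTE1",
        }
    for j, idx in enumerate(te_idx):
        enrichment[names[idx]] = {
            "tissue": tissue_pool[(j + 7) % len(tissue_pool)],
            "fold": cfg.te_fold,
            "class": "TE",
        }
    truth = PlantedTruth(
        loci=loci,
        species_membership=membership,
        enrichment=enrichment,
        baseline_expression={names[i]: float(baseline[i]) for i in range(cfg.n_loci)},
        reference_loci=[names[i] for i in sorted(ref_idx)],
        multimapper_name=multi_name,
        multimapper_sequence=multi_seq if cfg.plant_multimapper else None,
    )
    return genome, truth, species_sets


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def make_samples(cfg: SimulationConfig) -> SampleTable:
    rows = [
        {"sample_id": f"{t}_a{r + 1}", "animal_id": f"a{r + 1}", "tissue": t}
        for t in cfg.tissues
        for r in range(cfg.replicates)
    ]
    return SampleTable(pd.DataFrame(rows))


def expected_rpm(cfg: SimulationConfig, truth: PlantedTruth) -> pd.DataFrame:
    """Noise-free per-(locus, tissue) mean RPM implied by the planted design."""
    names = [l.name for l in truth.loci]
    out = pd.DataFrame(
        {t: [truth.baseline_expression[n] for n in names] for t in cfg.tissues},
        index=names,
    )
    for name, info in truth.enrichment.items():
        out.loc[name, info["tissue"]] *= info["fold"]
    return out


def gen_counts(
    cfg: SimulationConfig, truth: PlantedTruth
) -> tuple[pd.DataFrame, SampleTable]:
    """Negative-binomial counts: Var = mu + dispersion * mu^2.

    mu[i, j] = depth * baseline_rpm_i * fold(i, tissue_j) / 1e6; dispersion 0
    degenerates to Poisson.
    """
    rng = cfg._rng("counts")
    samples = make_samples(cfg)
    mean_rpm = expected_rpm(cfg, truth)
    tissue_of = samples.tissue_of()
    mu = np.column_stack(
        [mean_rpm[tissue_of[s]].to_numpy() for s in samples.sample_ids]
    ) * (cfg.depth / 1e6)
    if cfg.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / cfg.dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
    df = pd.DataFrame(counts, index=mean_rpm.index, columns=samples.sample_ids)
    return df, samples


# ---------------------------------------------------------------------------
# read-level alignments
# ---------------------------------------------------------------------------

def gen_read_alignments(
    cfg: SimulationConfig,
    truth: PlantedTruth,
    sample_ids: list[str] | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Per-sample BED-like alignments drawn from the planted expression.

    Signal reads are the mature sequence shifted by at most
    ``(1 - read_overlap_guarantee) * locus_length`` bases, so every signal
    read passes the 70% coverage rule with a single genomic placement.
    ``decoy_fraction`` of reads fail counting by construction: half are
    placed away from any locus, half are stamped with the multi-mapper
    placement count (or also placed off-locus when no multi-mapper was
    planted).  Returns (alignments, per-locus signal-read bookkeeping,
    per-sample mapping statistics).
    """
    rng = cfg._rng("reads")
    samples = make_samples(cfg)
    if sample_ids is None:
        # one replicate per tissue keeps the read-level files small
        sample_ids = [f"{t}_a1" for t in cfg.tissues]
    unknown = set(sample_ids) - set(samples.sample_ids)
    if unknown:
        raise ConfigError(f"unknown sample ids {sorted(unknown)}")
    mean_rpm = expected_rpm(cfg, truth)
    tissue_of = samples.tissue_of()
    loci = truth.loci
    max_shift = {
        l.name: int((1.0 - cfg.read_overlap_guarantee) * (l.end - l.start))
        for l in loci
    }
    # intergenic decoy placement: keep away from every planted locus
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for l in loci:
        by_chrom.setdefault(l.chrom, []).append((l.start, l.end))
    chrom_names = sorted({l.chrom for l in loci})

    def decoy_position(length: int) -> tuple[str, int]:
        while True:
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            pos = int(rng.integers(0, cfg.chrom_length - length))
            ok = True
            for ls, le in by_chrom.get(chrom, ()):
                ov = min(pos + length, le) - max(pos, ls)
                if ov > 0 and ov / (le - ls) >= 0.5:
                    ok = False
                    break
            if ok:
                return chrom, pos

    alignments: dict[str, pd.DataFrame] = {}
    bookkeeping = pd.DataFrame(
        0, index=[l.name for l in loci], columns=sample_ids, dtype=int
    )
    stats_rows = []
    for sample in sample_ids:
        tissue = tissue_of[sample]
        probs = mean_rpm[tissue].to_numpy()
        probs = probs / probs.sum()
        n_decoy = int(round(cfg.decoy_fraction * cfg.alignment_depth))
        n_signal = cfg.alignment_depth - n_decoy
        per_locus = rng.multinomial(n_signal, probs)
        rows = []
        rid = 0
        for li, l in enumerate(loci):
            L = l.end - l.start
            ms = max_shift[l.name]
            shifts = (
                rng.integers(-ms, ms + 1, per_locus[li])
                if ms > 0
                else np.zeros(per_locus[li], dtype=int)
            )
            for sh in shifts:
                rows.append(
                    (l.chrom, l.start + int(sh), l.start + int(sh) + L,
                     f"{sample}:r{rid}", 1, l.strand)
                )
                rid += 1
        bookkeeping[sample] = per_locus
        n_multi = n_decoy // 2 if truth.multimapper_name else 0
        for _ in range(n_multi):
            length = len(truth.multimapper_sequence)
            chrom, pos = decoy_position(length)
            rows.append(
                (chrom, pos, pos + length, f"{sample}:r{rid}",
                 cfg.multimapper_copies, "+")
            )
            rid += 1
        for _ in range(n_decoy - n_multi):
            length = int(rng.integers(*cfg.locus_length))
            chrom, pos = decoy_position(length)
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((chrom, pos, pos + length, f"{sample}:r{rid}", 1, strand))
            rid += 1
        alignments[sample] = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "read_id", "n_hits", "strand"]
        )
        stats_rows.append(
            {
                "sample_id": sample,
                "aligned": len(rows),
                "total": int(round(len(rows) / cfg.mapped_fraction)),
            }
        )
    return alignments, bookkeeping, pd.DataFrame(stats_rows)


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

def gen_qpcr(
    cfg: SimulationConfig,
    expression: pd.DataFrame,
    targets: list[str],
    context: str = "tissue",
) -> pd.DataFrame:
    """Ct plates: Ct = intercept - slope * log2(expression) + N(0, sigma).

    Values above ``qpcr_ceiling`` are reported at the ceiling (instrument
    maximum); triplicates per (sample, target).  Zero expression maps to a
    deep Ct via a 2**-10 floor, i.e. censored downstream.
    """
    rng = cfg._rng("qpcr")
    rows = []
    expr = expression.clip(lower=2.0 ** -10)
    for target in targets:
        if target not in expr.index:
            raise ConfigError(f"qPCR target {target!r} not in expression matrix")
        log2e = np.log2(expr.loc[target].to_numpy(dtype=float))
        for j, sample in enumerate(expression.columns):
            for rep in range(1, cfg.qpcr_replicates + 1):
                ct = (
                    cfg.qpcr_intercept
                    - cfg.qpcr_slope * log2e[j]
                    + (rng.normal(0.0, cfg.qpcr_sigma) if cfg.qpcr_sigma else 0.0)
                )
                ct = float(np.clip(ct, 1.0, cfg.qpcr_ceiling))
                rows.append(
                    {"sample_id": sample, "target": target, "replicate": rep,
                     "ct": ct, "context": context}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# POC injury panel study
# ---------------------------------------------------------------------------

def gen_panel_study(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[float]]]:
    """Serum Ct plates + clinical chemistry for a repeat-dose study.

    Injured animals follow a rising latent injury level z(t); both ALT/AST
    (linear in z plus noise) and liver-target serum Ct (dropping
    ``injury_ct_gain`` cycles per unit z) are driven by the same z, giving
    the planted co-elevation.  Control animals stay at z = 0; non-liver
    targets are flat everywhere; reference targets are stable and abundant.
    """
    rng = cfg._rng("panel")
    if cfg.n_injured + cfg.n_control < 2 or len(cfg.panel_days) < 2:
        raise ConfigError("panel study needs >= 2 animals and >= 3 timepoints")
    animals = [f"dog{i + 1}" for i in range(cfg.n_injured + cfg.n_control)]
    injured = set(animals[: cfg.n_injured])
    timepoints = [(d, ph) for d in cfg.panel_days for ph in ("predose", "postdose")]
    if len(cfg.injury_trajectory) != len(timepoints):
        raise ConfigError("injury_trajectory length must match day x phase grid")

    injury: dict[str, list[float]] = {}
    chem_rows, ct_rows = [], []
    targets = (
        [(t, cfg.liver_ct_base, True) for t in cfg.liver_targets]
        + [(t, cfg.nonliver_ct_base, False) for t in cfg.nonliver_targets]
        + [(t, cfg.reference_ct_base, False) for t in cfg.reference_targets]
    )
    for animal in animals:
        z = list(cfg.injury_trajectory) if animal in injured else [0.0] * len(timepoints)
        injury[animal] = z
        for k, (day, phase) in enumerate(timepoints):
            chem_rows.append(
                {
                    "animal": animal, "day": day, "phase": phase,
                    "ALT": round(
                        max(1.0, cfg.alt_base + cfg.alt_gain * z[k]
                            + rng.normal(0, cfg.alt_sigma)), 2),
                    "AST": round(
                        max(1.0, cfg.ast_base + cfg.ast_gain * z[k]
                            + rng.normal(0, cfg.ast_sigma)), 2),
                }
            )
            sample_id = f"{animal}_d{day}_{phase}"
            for target, base, is_liver in targets:
                mean_ct = base - (cfg.injury_ct_gain * z[k] if is_liver else 0.0)
                for rep in range(1, cfg.qpcr_replicates + 1):
                    ct = mean_ct + rng.normal(0, cfg.panel_sigma)
                    ct = float(np.clip(ct, 1.0, cfg.qpcr_ceiling))
                    ct_rows.append(
                        {"sample_id": sample_id, "animal": animal, "day": day,
                         "phase": phase, "target": target, "replicate": rep,
                         "ct": round(ct, 4), "context": "serum"}
                    )
    return pd.DataFrame(ct_rows), pd.DataFrame(chem_rows), injury


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_fasta(records: dict[str, str] | list[MatureSequence],
                path: str | Path, width: int = 80) -> None:
    with Path(path).open("w") as fh:
        if isinstance(records, dict):
            items = records.items()
        else:
            items = [(r.name, r.sequence) for r in records]
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def simulate_all(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write every pipeline input with ground truth under ``outdir``.

    Emits genome.fa, per-species mature FASTAs, samples.tsv, counts.tsv,
    alignments/<sample>.bed, mapping_stats.tsv, ct.csv (tissue plates for
    reference + a subset of planted enriched loci), serum_ct.csv, chem.csv
    and truth.json.  Byte-identical across reruns at a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth, species_sets = gen_genome_and_annotation(cfg)
    write_fasta(genome, outdir / "genome.fa")
    paths = {"genome": outdir / "genome.fa"}
    for sp, seqs in species_sets.items():
        write_fasta(seqs, outdir / f"{sp}.fa")
        paths[f"species_{sp}"] = outdir / f"{sp}.fa"

    counts, samples = gen_counts(cfg, truth)
    samples.write_tsv(outdir / "samples.tsv")
    counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="locus")
    paths["samples"] = outdir / "samples.tsv"
    paths["counts"] = outdir / "counts.tsv"

    alignments, bookkeeping, stats = gen_read_alignments(cfg, truth)
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for sample, df in alignments.items():
        df.to_csv(aln_dir / f"{sample}.bed", sep="\t", header=False, index=False)
    bookkeeping.to_csv(outdir / "read_truth.tsv", sep="\t", index_label="locus")
    stats.to_csv(outdir / "mapping_stats.tsv", sep="\t", index=False)
    paths["alignments"] = aln_dir
    paths["mapping_stats"] = outdir / "mapping_stats.tsv"

    rpm = counts / counts.sum(axis=0).replace(0, 1) * 1e6
    qpcr_targets = truth.reference_loci + sorted(truth.enrichment)[:12]
    ct = gen_qpcr(cfg, rpm, qpcr_targets)
    ct.to_csv(outdir / "ct.csv", index=False)
    paths["ct"] = outdir / "ct.csv"

    serum_ct, chem, injury = gen_panel_study(cfg)
    truth.injury_profile = injury
    serum_ct.to_csv(outdir / "serum_ct.csv", index=False)
    chem.to_csv(outdir / "chem.csv", index=False)
    truth.save(outdir / "truth.json")
    paths["serum_ct"] = outdir / "serum_ct.csv"
    paths["chem"] = outdir / "chem.csv"
    paths["truth"] = outdir / "truth.json"
    return paths


def config_to_dict(cfg: SimulationConfig) -> dict:
    return dataclasses.asdict(cfg)
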