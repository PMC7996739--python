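"""Self-contained synthetic test worlds: toy genomes with implanted
miRNA-like hairpins, family bundles, decoys and mutation series.

The generator emulates the canonical precursor geometry — a nearly
symmetric stem-loop with the mature miR on one arm and its miR* partner
on the other — so every pipeline stage can be exercised, end to end,
without any external data.  Implanted hairpins are guaranteed by
construction check to pass the structural filters at zero mutations;
decoys are dinucleotide-shuffled hairpins (same composition, structure
destroyed).  Background sequence is i.i.d. uniform; all randomness comes
from a single numpy PCG64 generator, so a fixed seed reproduces the
world byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import Thresholds
from .formats_io import (
    Feature,
    StockholmAlignment,
    reverse_complement,
    write_fasta,
    write_gff3,
    write_stockholm,
)
from .homology import FamilyCutoffs
from .intervals import GenomicInterval
from .mature import MatureSequence, MirnaFamily
from .structure import check_arm_consistency, fold_mfe

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

MIR_LENGTH = 22
MIR_OFFSET = 2  # nt into the 5' arm where the miR window starts


@dataclass
class Hairpin:
    """A constructed precursor with known mature coordinates (DNA)."""

    name: str
    sequence: str
    dotbracket: str
    mir_interval: tuple[int, int]
    mirstar_interval: tuple[int, int]
    mfe: float

    @property
    def mir_sequence(self) -> str:
        return self.sequence[slice(*self.mir_interval)].replace("T", "U")

    @property
    def mirstar_sequence(self) -> str:
        return self.sequence[slice(*self.mirstar_interval)].replace("T", "U")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def make_hairpin(
    stem_len: int,
    loop_len: int,
    rng: np.random.Generator,
    name: str = "hairpin",
    gu_fraction: float = 0.10,
    mismatch_fraction: float = 0.08,
    bulge_rate: float = 0.04,
    max_tries: int = 100,
) -> Hairpin:
    """Construct a stem-loop precursor that passes the structural filters.

    The sequence is stem + loop + reverse-complement(stem), perturbed the
    way real precursor stems are imperfect: ~10% of stem positions become
    G-U wobbles, ~8% internal mismatches, and the 3' arm receives the
    occasional 1-nt bulge.  That keeps the folding stability near the
    ~-0.3 to -0.6 kcal/mol/nt of genuine pre-miRNA hairpins instead of
    the unrealistically robust perfect-complement stem.  Candidates are
    folded and re-drawn until the MFE structure is a single hairpin with
    MFE <= -10 kcal/mol and valid arm placements (bounded at
    ``max_tries`` draws).
    """
    if not 25 <= stem_len <= 45:
        raise ValueError("stem_len must lie in [25, 45]")
    if not 4 <= loop_len <= 15:
        raise ValueError("loop_len must lie in [4, 15]")
    thr = Thresholds()
    for _ in range(max_tries):
        stem = list(_random_seq(rng, stem_len))
        partner = [_COMPLEMENT[c] for c in stem][::-1]
        for i in range(stem_len):
            r = rng.random()
            if r < gu_fraction:
                # G-U wobble: 5' side G pairs 3' side T
                stem[i] = "G"
                partner[stem_len - 1 - i] = "T"
            elif r < gu_fraction + mismatch_fraction:
                # internal mismatch: partner becomes non-complementary
                options = [b for b in "ACGT" if b != _COMPLEMENT[stem[i]]]
                partner[stem_len - 1 - i] = options[int(rng.integers(0, 3))]
        loop = _random_seq(rng, loop_len)
        arm3 = list("".join(partner))
        # occasional single-nt bulges on the 3' arm
        for _ in range(2):
            if rng.random() < bulge_rate * stem_len / 2:
                pos = int(rng.integers(1, len(arm3)))
                arm3.insert(pos, str(rng.choice(_BASES)))
        sequence = "".join(stem) + loop + "".join(arm3)

        fold = fold_mfe(sequence)
        if fold.mfe > thr.mfe_max:
            continue
        mir = (MIR_OFFSET, MIR_OFFSET + MIR_LENGTH)
        mirstar = _paired_window(fold.dotbracket, mir)
        if mirstar is None:
            continue
        if not 15 <= mirstar[1] - mirstar[0] <= 30:
            continue
        verdict = check_arm_consistency(
            mir, mirstar, fold.dotbracket, thr.loop_overlap_tolerance
        )
        if verdict != "valid":
            continue
        return Hairpin(name, sequence, fold.dotbracket, mir, mirstar, fold.mfe)
    raise RuntimeError(f"could not construct a valid hairpin in {max_tries} tries")


def _paired_window(dotbracket: str, mir: tuple[int, int]) -> tuple[int, int] | None:
    from .structure import pair_table

    pt = pair_table(dotbracket)
    partners = [pt[i] for i in range(*mir) if pt[i] >= 0]
    partners = [p for p in partners if p < mir[0] or p >= mir[1]]
    if len(partners) < 10:
        return None
    return (min(partners), max(partners) + 1)


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle preserving dinucleotide composition (Altschul–Erikson:
    shuffle the edge multiset of the dinucleotide graph and rebuild an
    Eulerian walk with the original start and end states)."""
    if len(sequence) < 3:
        return sequence
    edges: dict[str, list[str]] = {}
    for a, b in zip(sequence, sequence[1:]):
        edges.setdefault(a, []).append(b)
    last = sequence[-1]
    for _ in range(200):
        trial = {k: list(rng.permutation(v)) for k, v in edges.items()}
        out = [sequence[0]]
        stacks = {k: list(v) for k, v in trial.items()}
        try:
            while len(out) < len(sequence):
                out.append(stacks[out[-1]].pop(0))
        except (KeyError, IndexError):
            continue
        if out[-1] == last:
            return "".join(out)
    return "".join(out)  # best effort; composition still preserved


def mutation_series(
    locus_sequence: str, counts: list[int], rng: np.random.Generator
) -> list[str]:
    """Nested point-mutation series: for each k in the increasing
    ``counts``, exactly k distinct positions carry a substitution, and
    mutations accumulate along the series (mirroring an increasing
    mismatch load on the same locus)."""
    if counts != sorted(counts):
        raise ValueError("counts must be increasing")
    if counts and counts[-1] > len(locus_sequence):
        raise ValueError("cannot mutate more positions than the sequence has")
    order = rng.permutation(len(locus_sequence))
    seq = list(locus_sequence)
    out = []
    mutated = 0
    for k in counts:
        while mutated < k:
            pos = int(order[mutated])
            alternatives = [b for b in "ACGT" if b != seq[pos]]
            seq[pos] = alternatives[int(rng.integers(0, 3))]
            mutated += 1
        out.append("".join(seq))
    return out


@dataclass
class SyntheticWorld:
    """A toy genome with ground truth: implanted hairpins, their family
    bundles, and structure-destroyed decoy loci."""

    genome: dict[str, str]
    truth: list[Feature]
    decoy_loci: list[Feature]
    families: list[MirnaFamily]
    hairpins: list[Hairpin]
    seed: int
    hit_tables: dict[str, list[str]] = field(default_factory=dict)  # family -> blast6 lines

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.genome.values())

    @property
    def truth_precursors(self) -> list[Feature]:
        return [f for f in self.truth if f.feature_type == "pre_miRNA"]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome.items(), outdir / "genome.fa")
        lengths = {k: len(v) for k, v in self.genome.items()}
        write_gff3(self.truth, outdir / "truth.gff3", lengths)
        write_gff3(self.decoy_loci, outdir / "decoys.gff3", lengths)
        famdir = outdir / "families"
        famdir.mkdir(exist_ok=True)
        for fam in self.families:
            write_stockholm(fam.precursor_alignment, famdir / f"{fam.family_id}.stk")
            write_fasta(
                [(m.mature_id, m.sequence) for m in fam.mature_sequences],
                famdir / f"{fam.family_id}_mature.fa",
            )
        hitdir = outdir / "hits"
        hitdir.mkdir(exist_ok=True)
        for family_id, lines in self.hit_tables.items():
            (hitdir / f"{family_id}.blast-tab6.tsv").write_text(
                "".join(line + "\n" for line in lines)
            )


def build_family(
    hairpin: Hairpin,
    rng: np.random.Generator,
    n_members: int = 5,
    n_mutations: int = 3,
    max_tries: int = 20,
) -> MirnaFamily:
    """Family bundle from a hairpin: 5 sibling precursors (same stem,
    +/- 3 substitutions each), SS_cons = the construction structure,
    matures = the implanted miR (5p) and miR* (3p).

    Curated family alignments contain genuine precursors, so each
    sibling is itself required to be a valid hairpin (stable fold,
    placeable matures, consistent arms); failing draws are repeated."""
    matures = [
        MatureSequence(f"{hairpin.name}-5p", hairpin.mir_sequence, "5p"),
        MatureSequence(f"{hairpin.name}-3p", hairpin.mirstar_sequence, "3p"),
    ]
    rows = {}
    for i in range(n_members):
        for _ in range(max_tries):
            sib = mutation_series(hairpin.sequence, [n_mutations], rng)[0]
            if _valid_precursor(sib, matures):
                break
        rows[f"{hairpin.name}_m{i + 1}"] = sib.replace("T", "U")
    alignment = StockholmAlignment(
        family_id=hairpin.name,
        rows=rows,
        consensus_structure=hairpin.dotbracket,
    )
    return MirnaFamily(hairpin.name, alignment, matures)


def _valid_precursor(sequence: str, matures: list[MatureSequence]) -> bool:
    """Fold-level validity used during family construction: stable MFE,
    placeable matures, single stem-loop with consistent arms."""
    import types

    from .mature import locate_mature

    thr = Thresholds()
    rna = sequence.replace("T", "U")
    fold = fold_mfe(rna)
    if fold.mfe > thr.mfe_max:
        return False
    shim = types.SimpleNamespace(mature_sequences=matures)
    placement = locate_mature(rna, shim, thr)
    if placement is None:
        return False
    verdict = check_arm_consistency(
        placement.mir_interval,
        placement.mirstar_interval,
        fold.dotbracket,
        thr.loop_overlap_tolerance,
    )
    return verdict == "valid"


def implant(
    genome_length: int = 1_000_000,
    n_hairpins: int = 20,
    n_decoys: int = 20,
    seed: int = 1,
    chromosome: str = "chrS",
) -> SyntheticWorld:
    """Build a synthetic world: uniform background, non-overlapping
    implants at random positions and strands, truth/decoy annotation and
    per-family pre-computed homology hit tables (the over-sensitive
    search scenario: every implant, decoys included, reaches the filter
    cascade)."""
    rng = np.random.default_rng(seed)
    hairpins = [
        make_hairpin(
            stem_len=int(rng.integers(28, 42)),
            loop_len=int(rng.integers(5, 12)),
            rng=rng,
            name=f"fam{i + 1:02d}",
        )
        for i in range(n_hairpins)
    ]
    decoy_seqs = [
        dinucleotide_shuffle(hairpins[i % n_hairpins].sequence, rng)
        for i in range(n_decoys)
    ]

    inserts = [h.sequence for h in hairpins] + decoy_seqs
    total_insert = sum(len(s) for s in inserts)
    margin = 80
    if genome_length < total_insert + margin * (len(inserts) + 1):
        raise ValueError("genome too small for the requested implants")

    background = _random_seq(rng, genome_length)
    positions = _place_non_overlapping(
        rng, genome_length, [len(s) + 2 * margin for s in inserts]
    )
    strands = ["+" if rng.random() < 0.5 else "-" for _ in inserts]

    genome_chars = list(background)
    truth: list[Feature] = []
    decoys: list[Feature] = []
    hit_tables: dict[str, list[str]] = {}
    for idx, (seq, pos, strand) in enumerate(zip(inserts, positions, strands)):
        start = pos + margin
        placed = seq if strand == "+" else reverse_complement(seq)
        genome_chars[start : start + len(seq)] = list(placed)
        iv = GenomicInterval(chromosome, start, start + len(seq), strand)
        is_truth = idx < n_hairpins
        if is_truth:
            hp = hairpins[idx]
            ft = Feature(
                interval=iv,
                feature_id=f"truth_{hp.name}",
                feature_type="pre_miRNA",
                family=hp.name,
                attributes={
                    "mir": f"{hp.mir_interval[0]}-{hp.mir_interval[1]}",
                    "mirstar": f"{hp.mirstar_interval[0]}-{hp.mirstar_interval[1]}",
                },
            )
            truth.append(ft)
            for tag, local in (("miR", hp.mir_interval), ("miR*", hp.mirstar_interval)):
                if strand == "+":
                    g = (start + local[0], start + local[1])
                else:
                    g = (start + len(seq) - local[1], start + len(seq) - local[0])
                truth.append(
                    Feature(
                        interval=GenomicInterval(chromosome, g[0], g[1], strand),
                        feature_id=f"truth_{hp.name}_{tag}",
                        feature_type="miRNA",
                        family=hp.name,
                        attributes={"Parent": f"truth_{hp.name}"},
                    )
                )
            family_id = hp.name
            coverage_span = len(hp.sequence)
            evalue, bitscore, pident = 1e-20, 2.0 * len(seq), 100.0
        else:
            hp = hairpins[(idx - n_hairpins) % n_hairpins]
            ft = Feature(
                interval=iv,
                feature_id=f"decoy_{idx - n_hairpins + 1:02d}",
                feature_type="decoy",
                family=hp.name,
            )
            decoys.append(ft)
            family_id = hp.name
            coverage_span = max(20, math.ceil(0.8 * len(hp.sequence)))
            evalue, bitscore, pident = 1e-6, 45.0, 82.0
        sstart, send = (start + 1, start + len(seq)) if strand == "+" else (
            start + len(seq), start + 1,
        )
        hit_tables.setdefault(family_id, []).append(
            "\t".join(
                map(
                    str,
                    [
                        family_id, chromosome, pident, len(seq), 0, 0,
                        1, coverage_span, sstart, send,
                        f"{evalue:g}", f"{bitscore:.1f}",
                    ],
                )
            )
        )

    genome = {chromosome: "".join(genome_chars)}
    families = [build_family(hp, rng) for hp in hairpins]
    genome_size = genome_length
    for fam in families:
        fam.cutoffs = FamilyCutoffs(genome_size=genome_size)
    return SyntheticWorld(
        genome=genome,
        truth=truth,
        decoy_loci=decoys,
        families=families,
        hairpins=hairpins,
        seed=seed,
        hit_tables=hit_tables,
    )


def _place_non_overlapping(
    rng: np.random.Generator, genome_length: int, sizes: list[int], max_tries: int = 10000
) -> list[int]:
    placed: list[tuple[int, int]] = []
    out: list[int] = []
    for size in sizes:
        for _ in range(max_tries):
            pos = int(rng.integers(0, genome_length - size))
            if all(pos + size <= s or pos >= e for s, e in placed):
                placed.append((pos, pos + size))
                out.append(pos)
                break
        else:
            raise ValueError("genome too small for non-overlapping placement")
    return out
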