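"""Protein-level architecture, subset labels and family summary tables.

Two adjacent fingers are *linked* when fewer than 12 residues separate them
(gap <= 11); maximal runs of linked fingers form tandem arrays.  A protein is
*tandem* when at least one array holds two or more fingers, otherwise
*isolated*.  Subset labels follow the ten-subset scheme used for plant C2H2
families (Ta-t1-SF, Ta-t2-SF, Ta-1i-{Q,M,Z,D}-SF, Ta-2i-{Q,M,Z,Mix}-SF,
Ta-3i-SF, Ta-4i-SF).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import pandas as pd

from zfsurvey.errors import ZfSurveyError
from zfsurvey.sequence_io import GeneLocus, GeneModel
from zfsurvey.zf_scan import ZFDomain

logger = logging.getLogger(__name__)

#: largest inter-finger gap that still links two fingers into a tandem array
TANDEM_MAX_GAP = 11

SUBSETS = (
    "Ta-t1-SF", "Ta-t2-SF",
    "Ta-1i-Q-SF", "Ta-1i-M-SF", "Ta-1i-Z-SF", "Ta-1i-D-SF",
    "Ta-2i-Q-SF", "Ta-2i-M-SF", "Ta-2i-Z-SF", "Ta-2i-Mix-SF",
    "Ta-3i-SF", "Ta-4i-SF",
)


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered fingers of one protein plus the inter-finger gaps."""

    protein_id: str
    domains: tuple[ZFDomain, ...]
    gaps: tuple[int, ...]


@dataclass(frozen=True)
class SubsetAssignment:
    protein_id: str
    arrangement: str          # "tandem" | "isolated"
    subset: str
    n_domains: int
    type_string: str          # e.g. "M3;M4;M4;M4;Z1"


def collapse_type(dtype: str) -> str:
    """M1..M4 -> M, Z1/Z2 -> Z; Q and D unchanged."""
    if dtype.startswith("M"):
        return "M"
    if dtype.startswith("Z"):
        return "Z"
    return dtype


def build_architecture(domains: Sequence[ZFDomain]) -> DomainArchitecture:
    """Assemble sorted, non-overlapping fingers of one protein; compute gaps."""
    if not domains:
        raise ZfSurveyError("cannot build an architecture from zero domains")
    ids = {d.protein_id for d in domains}
    if len(ids) != 1:
        raise ZfSurveyError(f"domains belong to multiple proteins: {sorted(ids)}")
    ordered = sorted(domains, key=lambda d: d.start)
    gaps = []
    for a, b in zip(ordered, ordered[1:]):
        gap = b.start - a.end
        if gap < 0:
            raise ZfSurveyError(
                f"{a.protein_id}: overlapping domains at [{a.start},{a.end}) "
                f"and [{b.start},{b.end})"
            )
        gaps.append(gap)
    return DomainArchitecture(
        protein_id=ordered[0].protein_id, domains=tuple(ordered), gaps=tuple(gaps)
    )


def classify_arrangement(
    arch: DomainArchitecture, tandem_max_gap: int = TANDEM_MAX_GAP
) -> tuple[str, list[list[int]]]:
    """Return (arrangement, tandem-array partition as domain-index runs).

    Adjacent fingers are linked iff their gap <= ``tandem_max_gap``; the
    partition lists maximal linked runs (singletons included).  The protein is
    tandem iff some run holds >= 2 fingers.
    """
    runs: list[list[int]] = [[0]]
    for i, gap in enumerate(arch.gaps):
        if gap <= tandem_max_gap:
            runs[-1].append(i + 1)
        else:
            runs.append([i + 1])
    arrangement = "tandem" if any(len(r) >= 2 for r in runs) else "isolated"
    return arrangement, runs


def assign_subset(
    arch: DomainArchitecture,
    arrangement: Optional[str] = None,
    tandem_max_gap: int = TANDEM_MAX_GAP,
) -> SubsetAssignment:
    """Map an architecture to one of the ten family subsets.

    Isolated proteins are labelled by finger count and collapsed type
    (1i-{Q,M,Z,D}; 2i-{Q,M,Z} when both fingers agree, else 2i-Mix; 3i; 4i —
    proteins with five or more dispersed fingers are binned into Ta-4i-SF with
    a logged warning).  Tandem proteins are Ta-t1-SF when a single tandem
    array covers every finger, Ta-t2-SF otherwise (several arrays, or an array
    plus isolated extras).
    """
    computed, runs = classify_arrangement(arch, tandem_max_gap)
    if arrangement is None:
        arrangement = computed
    types = [d.dtype for d in arch.domains]
    collapsed = [collapse_type(t) for t in types]
    n = len(types)

    if arrangement == "tandem":
        full_single_array = len(runs) == 1
        subset = "Ta-t1-SF" if full_single_array else "Ta-t2-SF"
    elif n == 1:
        subset = f"Ta-1i-{collapsed[0]}-SF"
    elif n == 2:
        if collapsed[0] == collapsed[1] and collapsed[0] in ("Q", "M", "Z"):
            subset = f"Ta-2i-{collapsed[0]}-SF"
        else:
            subset = "Ta-2i-Mix-SF"
    elif n == 3:
        subset = "Ta-3i-SF"
    else:
        if n > 4:
            logger.warning(
                "%s has %d dispersed fingers; binned into Ta-4i-SF",
                arch.protein_id, n,
            )
        subset = "Ta-4i-SF"

    return SubsetAssignment(
        protein_id=arch.protein_id,
        arrangement=arrangement,
        subset=subset,
        n_domains=n,
        type_string=";".join(types),
    )


def dedupe_variants(
    assignments: Sequence[SubsetAssignment],
    gene_of: Mapping[str, tuple[str, Optional[int]]],
) -> tuple[dict[str, SubsetAssignment], pd.DataFrame]:
    """Pick one representative per gene and flag architecture-divergent genes.

    ``gene_of`` maps protein_id -> (gene_id, variant).  The representative is
    the lowest variant index (variant-less ids sort first).  A gene is flagged
    when its splice variants disagree in type_string.
    """
    groups: dict[str, list[SubsetAssignment]] = {}
    for a in assignments:
        gene_id, _ = gene_of[a.protein_id]
        groups.setdefault(gene_id, []).append(a)

    reps: dict[str, SubsetAssignment] = {}
    rows = []
    for gene_id, members in groups.items():
        members.sort(key=lambda a: (gene_of[a.protein_id][1] is not None,
                                    gene_of[a.protein_id][1] or 0))
        rep = members[0]
        reps[gene_id] = rep
        divergent = len({m.type_string for m in members}) > 1
        rows.append({
            "gene_id": gene_id,
            "n_variants": len(members),
            "representative": rep.protein_id,
            "architecture_divergent": divergent,
            "type_strings": "|".join(sorted({m.type_string for m in members})),
        })
    report = pd.DataFrame(
        rows, columns=["gene_id", "n_variants", "representative",
                       "architecture_divergent", "type_strings"]
    ).sort_values("gene_id").reset_index(drop=True)
    return reps, report


def count_introns(model: GeneModel) -> int:
    """Intron count of one gene model: exons minus one."""
    if not model.exons:
        raise ZfSurveyError(f"{model.mrna_id} has no exons")
    return len(model.exons) - 1


def percent(count: int, total: int, places: int = 1) -> str:
    """Exact half-up percentage formatting, e.g. percent(214, 457) == '46.8'."""
    if total == 0:
        return f"{Decimal(0):.{places}f}"
    frac = Decimal(100) * Decimal(count) / Decimal(total)
    q = Decimal(1).scaleb(-places)
    return str(frac.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FamilySummary:
    """Family-level tallies.  Counts are exact integers; percentages are the
    half-up formatted strings alongside exact fractions.

    Protein-level denominators use the number of classified proteins;
    gene-level denominators (chromosome/arm/subgenome/introns) use the number
    of unique genes with a parsed locus.
    """

    n_proteins: int
    n_genes: int
    subset_counts: dict[str, int]
    tandem_count: int
    isolated_count: int
    tandem_pct: str
    isolated_pct: str
    chromosome_counts: dict[int, int] = field(default_factory=dict)
    chromosome_pct: dict[int, str] = field(default_factory=dict)
    chrom_subgenome: dict[tuple[int, str], int] = field(default_factory=dict)
    subgenome_counts: dict[str, int] = field(default_factory=dict)
    subgenome_pct: dict[str, str] = field(default_factory=dict)
    arm_counts: dict[str, int] = field(default_factory=dict)
    arm_pct: dict[str, str] = field(default_factory=dict)
    chrom_arm: dict[tuple[int, str], int] = field(default_factory=dict)
    intron_histogram: dict[int, int] = field(default_factory=dict)
    intronless_genes: int = 0
    unparsed_locus_genes: int = 0
    fractions: dict[str, Fraction] = field(default_factory=dict)


def summarize_family(
    assignments: Sequence[SubsetAssignment],
    loci: Mapping[str, Optional[GeneLocus]],
    models: Optional[Sequence[GeneModel]] = None,
) -> FamilySummary:
    """Tally subsets, arrangements, genomic placement and intron structure.

    ``loci`` maps gene_id -> locus (None for ids outside the Traes dialect;
    such genes are skipped in placement tables with a logged count).  Protein
    percentages are one-decimal; sub-genome percentages two-decimal, mirroring
    the mixed precision conventional in family-survey reports.
    """
    if not assignments:
        raise ZfSurveyError("summarize_family needs at least one assignment")

    n_proteins = len(assignments)
    subset_counts = {s: 0 for s in SUBSETS}
    tandem = isolated = 0
    for a in assignments:
        subset_counts[a.subset] = subset_counts.get(a.subset, 0) + 1
        if a.arrangement == "tandem":
            tandem += 1
        else:
            isolated += 1

    genes = list(loci.keys())
    n_genes = len(genes)
    placed = {g: l for g, l in loci.items() if l is not None}
    unparsed = n_genes - len(placed)
    if unparsed:
        logger.info("%d genes lack a parseable Traes locus; skipped in placement tables",
                    unparsed)
    denom = len(placed)

    chromosome_counts: dict[int, int] = {c: 0 for c in range(1, 8)}
    chrom_subgenome: dict[tuple[int, str], int] = {}
    subgenome_counts: dict[str, int] = {"A": 0, "B": 0, "D": 0}
    arm_counts: dict[str, int] = {"S": 0, "L": 0}
    chrom_arm: dict[tuple[int, str], int] = {}
    for locus in placed.values():
        chromosome_counts[locus.chromosome] += 1
        subgenome_counts[locus.subgenome] += 1
        arm_counts[locus.arm] += 1
        chrom_subgenome[(locus.chromosome, locus.subgenome)] = (
            chrom_subgenome.get((locus.chromosome, locus.subgenome), 0) + 1
        )
        chrom_arm[(locus.chromosome, locus.arm)] = (
            chrom_arm.get((locus.chromosome, locus.arm), 0) + 1
        )

    intron_histogram: dict[int, int] = {}
    intronless = 0
    if models:
        for m in models:
            k = count_introns(m)
            intron_histogram[k] = intron_histogram.get(k, 0) + 1
            if k == 0:
                intronless += 1

    fractions = {
        "tandem": Fraction(tandem, n_proteins),
        "isolated": Fraction(isolated, n_proteins),
    }
    if denom:
        for sub, cnt in subgenome_counts.items():
            fractions[f"subgenome_{sub}"] = Fraction(cnt, denom)
        for arm, cnt in arm_counts.items():
            fractions[f"arm_{arm}"] = Fraction(cnt, denom)

    return FamilySummary(
        n_proteins=n_proteins,
        n_genes=n_genes,
        subset_counts=subset_counts,
        tandem_count=tandem,
        isolated_count=isolated,
        tandem_pct=percent(tandem, n_proteins, 1),
        isolated_pct=percent(isolated, n_proteins, 1),
        chromosome_counts=chromosome_counts,
        chromosome_pct={c: percent(n, denom, 1) for c, n in chromosome_counts.items()},
        chrom_subgenome=chrom_subgenome,
        subgenome_counts=subgenome_counts,
        subgenome_pct={s: percent(n, denom, 2) for s, n in subgenome_counts.items()},
        arm_counts=arm_counts,
        arm_pct={a: percent(n, denom, 2) for a, n in arm_counts.items()},
        chrom_arm=chrom_arm,
        intron_histogram=intron_histogram,
        intronless_genes=intronless,
        unparsed_locus_genes=unparsed,
        fractions=fractions,
    )


def assignments_to_table(
    assignments: Sequence[SubsetAssignment],
    gene_of: Optional[Mapping[str, tuple[str, Optional[int]]]] = None,
) -> pd.DataFrame:
    rows = [
        {
            "protein_id": a.protein_id,
            "gene_id": gene_of[a.protein_id][0] if gene_of else a.protein_id,
            "n_domains": a.n_domains,
            "type_string": a.type_string,
            "arrangement": a.arrangement,
            "subset": a.subset,
        }
        for a in assignments
    ]
    return pd.DataFrame(
        rows, columns=["protein_id", "gene_id", "n_domains", "type_string",
                       "arrangement", "subset"]
    )
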