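"""Synthetic inputs with planted ground truth.

Every input the survey consumes can be generated here with known truth:

* proteins with planted fingers of chosen types, spacings and arrangements
  (filler residues avoid C/H/F/L so no spurious fingers can arise),
* accessory boxes planted into flanks or inter-finger gaps,
* gene models with a chosen intron-count distribution,
* TPM matrices with planted expression groups,
* aligned codon pairs with controlled synonymous/nonsynonymous divergence,
* a "paper-counts" fixture: a full 457-protein / 204-gene family whose
  classification summary reproduces a fixed set of published-style tallies.

Structural tallies of the paper-counts fixture are independent of the seed;
the seed only varies filler residues and expression noise.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from zfsurvey.accessory_motifs import MotifHit, default_library
from zfsurvey.errors import SpecError
from zfsurvey.evolution import CODON_TO_AA, SENSE_CODONS, CodonPair, count_sites
from zfsurvey.expression import STAGE_CODES
from zfsurvey.sequence_io import (
    GeneLocus,
    GeneModel,
    ProteinRecord,
    compose_gene_id,
    write_gene_models,
    write_protein_fasta,
)
from zfsurvey.subset_classify import SubsetAssignment, assign_subset, build_architecture
from zfsurvey.zf_scan import QALGGH, ZFDomain, classify_domain

#: filler alphabet: no C or H (would seed spurious fingers), no F or L
#: (consensus-sensitive and present in every shipped EAR-like pattern)
FILLER = "ADEGIKMNPQRSTVWY"

#: substitution letters for degraded QALGGH windows (disjoint from QALGG)
DEGENERATE = "STNRKDE"

#: minimum gap after a D finger so the follower's first histidine lands more
#: than spacing_max (30) residues past the D's second cysteine
_MIN_GAP_AFTER_D = {"Q": 2, "M": 2, "Z1": 0, "Z2": 5}


@dataclass(frozen=True)
class ProteinSpec:
    """Blueprint of one synthetic protein.

    ``domain_types``: ordered finger type labels (Q, M1..M4, Z1, Z2, D);
    ``gaps``: residues between consecutive fingers (len = fingers - 1);
    ``planted_boxes``: (box name, context) pairs drawn from the default box
    library; ``seed`` drives filler residues only.
    """

    protein_id: str
    domain_types: tuple[str, ...]
    gaps: tuple[int, ...] = ()
    n_flank: int = 10
    c_flank: int = 10
    planted_boxes: tuple[tuple[str, str], ...] = ()
    seed: int = 0


def _filler(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(FILLER), size=n)) if n > 0 else ""


def _degenerate_window(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(DEGENERATE)) for _ in range(5))


def _mutated_window(rng: np.random.Generator, k: int) -> str:
    positions = sorted(rng.choice(5, size=k, replace=False))
    window = list(QALGGH[:5])
    for p in positions:
        window[p] = str(rng.choice(list(DEGENERATE)))
    return "".join(window)


def _build_block(dtype: str, rng: np.random.Generator) -> tuple[str, dict]:
    """One finger block; returns (text, ligand offsets relative to block start)."""
    if dtype == "Q":
        text = "C" + _filler(rng, 2) + "C" + _filler(rng, 7) + QALGGH + _filler(rng, 3) + "H"
        return text, {"c1": 0, "c2": 3, "h1": 16, "h2": 20}
    if dtype.startswith("M"):
        k = int(dtype[1:])
        if not 1 <= k <= 4:
            raise SpecError(f"unsupported M subclass {dtype!r}")
        win5 = _mutated_window(rng, k)
        text = "C" + _filler(rng, 2) + "C" + _filler(rng, 7) + win5 + "H" + _filler(rng, 3) + "H"
        return text, {"c1": 0, "c2": 3, "h1": 16, "h2": 20}
    if dtype == "Z1":   # spacing 14 (>= 12), fully degraded window
        text = ("C" + _filler(rng, 2) + "C" + _filler(rng, 9)
                + _degenerate_window(rng) + "H" + _filler(rng, 3) + "H")
        return text, {"c1": 0, "c2": 3, "h1": 18, "h2": 22}
    if dtype == "Z2":   # spacing 9 (< 12)
        text = ("C" + _filler(rng, 2) + "C" + _filler(rng, 4)
                + _degenerate_window(rng) + "H" + _filler(rng, 3) + "H")
        return text, {"c1": 0, "c2": 3, "h1": 13, "h2": 17}
    if dtype == "D":    # QALGGH present, second histidine absent
        text = "C" + _filler(rng, 2) + "C" + _filler(rng, 7) + QALGGH
        return text, {"c1": 0, "c2": 3, "h1": 16, "h2": None}
    raise SpecError(f"unknown finger type {dtype!r}")


def make_protein(spec: ProteinSpec) -> tuple[ProteinRecord, list[ZFDomain], list[MotifHit]]:
    """Emit a sequence whose scan+classify output equals the spec exactly.

    Returns (record, planted fingers, planted box hits).  Deterministic per
    seed; different seeds differ only in filler residues.
    """
    if len(spec.gaps) != max(len(spec.domain_types) - 1, 0):
        raise SpecError("gaps must have one entry fewer than domain_types")
    if any(g < 0 for g in spec.gaps):
        raise SpecError("gaps must be non-negative")
    if not spec.domain_types:
        raise SpecError("at least one finger type is required")
    if spec.n_flank < 0 or spec.c_flank < 0:
        raise SpecError("flanks must be non-negative")
    for i, dtype in enumerate(spec.domain_types[:-1]):
        if dtype != "D":
            continue
        nxt = spec.domain_types[i + 1]
        gap = spec.gaps[i]
        # a D finger scans by its His-free tail; an immediately adjacent
        # second D would place its window histidine inside that tail
        if nxt == "D" and gap < 1:
            raise SpecError("two adjacent D fingers need a gap of at least 1")
        # a full finger too close behind a D lets its histidines pair with
        # the D's cysteines into one chimeric C..C..H..H unit (spacing <= 30)
        min_gap = _MIN_GAP_AFTER_D.get(nxt if not nxt.startswith("M") else "M", 0)
        if nxt != "D" and gap < min_gap:
            raise SpecError(
                f"a D finger followed by {nxt} needs a gap of at least {min_gap} "
                "to keep the fingers separable"
            )

    rng = np.random.default_rng(spec.seed)
    parts: list[str] = [_filler(rng, spec.n_flank)]
    pos = spec.n_flank
    truth: list[ZFDomain] = []
    gap_spans: list[tuple[int, int]] = []   # free regions between fingers

    for i, dtype in enumerate(spec.domain_types):
        text, off = _build_block(dtype, rng)
        h2 = off["h2"]
        domain = ZFDomain(
            protein_id=spec.protein_id,
            c1=pos + off["c1"], c2=pos + off["c2"],
            h1=pos + off["h1"], h2=pos + h2 if h2 is not None else None,
            start=pos, end=pos + len(text),
            spacing=off["h1"] - off["c2"] - 1,
            window=text[off["h1"] - 5: off["h1"] + 1],
            mismatches=sum(1 for a, b in zip(text[off["h1"] - 5: off["h1"] + 1], QALGGH)
                           if a != b),
            ztype_spacing_rule=12,
            dtype="",
        )
        from dataclasses import replace
        domain = replace(domain, dtype=classify_domain(domain))
        if domain.dtype != dtype:
            raise SpecError(
                f"template for {dtype!r} classifies as {domain.dtype!r}"
            )
        truth.append(domain)
        parts.append(text)
        pos += len(text)
        if i < len(spec.gaps):
            gap_spans.append((pos, pos + spec.gaps[i]))
            parts.append(_filler(rng, spec.gaps[i]))
            pos += spec.gaps[i]

    c_flank_span = (pos, pos + spec.c_flank)
    parts.append(_filler(rng, spec.c_flank))
    seq = list("".join(parts))

    # plant accessory boxes
    library = {p.name: p for p in default_library()}
    planted: list[MotifHit] = []
    used: list[tuple[int, int]] = []

    def place(region: tuple[int, int], pattern_text: str, name: str,
              context_declared: str) -> None:
        length = len(pattern_text)
        for start in range(region[0], region[1] - length + 1):
            span = (start, start + length)
            if all(span[1] <= a or span[0] >= b for a, b in used):
                seq[span[0]:span[1]] = list(pattern_text)
                used.append(span)
                planted.append(MotifHit(
                    protein_id=spec.protein_id, name=name,
                    start=span[0], end=span[1], matched_text=pattern_text,
                    context_observed=context_declared, context_ok=True,
                ))
                return
        raise SpecError(f"no room to plant {name!r} in region {region}")

    for name, context in spec.planted_boxes:
        if name not in library or library[name].pattern is None:
            raise SpecError(f"{name!r} is not a concrete pattern in the default library")
        pattern = library[name].pattern
        text = "".join(str(rng.choice(list(FILLER))) if ch == "x" else ch
                       for ch in pattern)
        if context == "N-of-first-ZF":
            region = (0, spec.n_flank)
        elif context == "C-of-first-ZF":
            region = gap_spans[0] if gap_spans else c_flank_span
        elif context == "C-of-second-ZF":
            if len(spec.domain_types) < 2:
                raise SpecError("C-of-second-ZF needs at least two fingers")
            region = gap_spans[1] if len(gap_spans) > 1 else c_flank_span
        elif context in ("C-of-last-ZF", "anywhere"):
            region = c_flank_span
        else:
            raise SpecError(f"unsupported planted-box context {context!r}")
        place(region, text, name, context)

    record = ProteinRecord(
        id=spec.protein_id, sequence="".join(seq),
        gene_id=spec.protein_id.rsplit(".", 1)[0] if "." in spec.protein_id else spec.protein_id,
        variant=int(spec.protein_id.rsplit(".", 1)[1])
        if "." in spec.protein_id and spec.protein_id.rsplit(".", 1)[1].isdigit()
        else None,
    )
    return record, truth, planted


# ---------------------------------------------------------------------------
# codon pairs


def make_codon_pair(ks_target: float, ka_target: float, n_codons: int = 300,
                    seed: int = 0) -> tuple[CodonPair, dict]:
    """Simulate an aligned codon pair whose NG86 estimate centres on the targets.

    A random stop-free CDS is drawn; Poisson-distributed synonymous and
    nonsynonymous single-base changes are applied to a copy, with the Poisson
    means calibrated through the inverse Jukes-Cantor map
    p = (3/4)(1 - exp(-(4/3) K)) times the sequence's site counts.
    """
    if n_codons < 10:
        raise SpecError("n_codons must be at least 10")
    for name, target in (("ks_target", ks_target), ("ka_target", ka_target)):
        if not math.isfinite(target) or target < 0:
            raise SpecError(f"{name} must be finite and non-negative")
    ps_target = 0.75 * (1.0 - math.exp(-4.0 / 3.0 * ks_target))
    pn_target = 0.75 * (1.0 - math.exp(-4.0 / 3.0 * ka_target))
    if ps_target >= 0.745 or pn_target >= 0.745:
        raise SpecError("target divergence is at the Jukes-Cantor saturation bound")

    rng = np.random.default_rng(seed)
    codons = [str(c) for c in rng.choice(SENSE_CODONS, size=n_codons)]
    cds_a = "".join(codons)
    S0, N0 = count_sites(cds_a)

    n_syn = int(rng.poisson(ps_target * S0))
    n_nonsyn = int(rng.poisson(pn_target * N0))

    mutated = list(codons)
    hit_slots: set[tuple[int, int]] = set()   # one change per (codon, position)

    def options(synonymous: bool) -> list[tuple[int, int, str]]:
        opts = []
        for idx, codon in enumerate(mutated):
            aa = CODON_TO_AA[codon]
            for posn in range(3):
                if (idx, posn) in hit_slots:
                    continue
                for base in "ACGT":
                    if base == codon[posn]:
                        continue
                    alt = codon[:posn] + base + codon[posn + 1:]
                    alt_aa = CODON_TO_AA[alt]
                    if alt_aa == "*":
                        continue
                    if (alt_aa == aa) == synonymous:
                        opts.append((idx, posn, base))
        return opts

    applied_syn = applied_nonsyn = 0
    for synonymous, n_changes in ((True, n_syn), (False, n_nonsyn)):
        for _ in range(n_changes):
            opts = options(synonymous)
            if not opts:
                break
            idx, posn, base = opts[int(rng.integers(len(opts)))]
            codon = mutated[idx]
            mutated[idx] = codon[:posn] + base + codon[posn + 1:]
            hit_slots.add((idx, posn))
            if synonymous:
                applied_syn += 1
            else:
                applied_nonsyn += 1

    pair = CodonPair(id_a="sim_a", id_b="sim_b", cds_a=cds_a, cds_b="".join(mutated))
    truth = {
        "ks_target": ks_target, "ka_target": ka_target,
        "n_syn_applied": applied_syn, "n_nonsyn_applied": applied_nonsyn,
        "S0": S0, "N0": N0,
    }
    return pair, truth


# ---------------------------------------------------------------------------
# expression matrices


def make_expression(
    group_sizes: Sequence[int],
    group_profiles: Sequence[Sequence[float]],
    n_samples: int = 15,
    sigma: float = 0.3,
    seed: int = 0,
    gene_prefix: str = "gene",
) -> tuple[pd.DataFrame, pd.Series]:
    """TPM matrix with planted groups: per gene, log2 profile + Gaussian noise.

    ``group_profiles`` holds one per-sample log2(TPM+1) mean vector per group;
    the matrix is back-transformed to the TPM scale (clipped at zero).
    Returns (matrix, planted labels 1..len(group_sizes)).
    """
    if len(group_sizes) != len(group_profiles):
        raise SpecError("one profile per group is required")
    if any(s < 1 for s in group_sizes):
        raise SpecError("group sizes must be >= 1")
    rng = np.random.default_rng(seed)
    samples = list(STAGE_CODES[:n_samples]) if n_samples <= len(STAGE_CODES) else [
        f"S{i + 1}" for i in range(n_samples)
    ]
    rows, labels, gene_ids = [], [], []
    gene_no = 0
    for gidx, (size, profile) in enumerate(zip(group_sizes, group_profiles), start=1):
        profile = np.asarray(profile, dtype=float)
        if profile.shape != (n_samples,):
            raise SpecError(f"profile of group {gidx} must have {n_samples} values")
        for _ in range(size):
            gene_no += 1
            logvals = profile + rng.normal(0.0, sigma, size=n_samples)
            rows.append(np.clip(2.0 ** logvals - 1.0, 0.0, None))
            labels.append(gidx)
            gene_ids.append(f"{gene_prefix}{gene_no:04d}")
    matrix = pd.DataFrame(rows, index=gene_ids, columns=samples)
    return matrix, pd.Series(labels, index=gene_ids, name="group")


# ---------------------------------------------------------------------------
# the paper-counts fixture


#: finger-architecture templates (types, gaps)
_TANDEM_ARCHS = (
    (("M1", "M2"), (5,)),                  # one tandem array -> Ta-t1-SF
    (("M1", "M2", "Z1"), (5, 40)),         # array + isolated extra -> Ta-t2-SF
)
_ISOLATED_ARCHS = (
    (("Q",), ()),
    (("M2",), ()),
    (("Z1",), ()),
    (("D",), ()),
    (("Q", "Q"), (20,)),
    (("M1", "M3"), (20,)),
    (("Z1", "Z2"), (20,)),
    (("M4", "Z1"), (40,)),
    (("Q", "M1", "Z2"), (20, 20)),
    (("Q", "M1", "Z1", "D"), (15, 15, 15)),
)

#: per-chromosome gene totals; chr 2/3/4/5/7 are published-style, 1/6 free margins
_CHR_TOTALS = {1: 20, 2: 38, 3: 27, 4: 33, 5: 54, 6: 19, 7: 13}
#: long-arm gene quotas per chromosome (sum 115); chr 2/5/7 published-style
_CHR_LONG = {1: 9, 2: 14, 3: 14, 4: 16, 5: 48, 6: 7, 7: 7}

_N_GENES = 204
_N_B = 85       # sub-genome B genes
_N_A = 60

#: expression group log2 profiles: (root level x3, non-root level x12)
_GROUP_PROFILES = {
    "I": (0.4, 0.4),
    "II_mod": (6.0, 2.0),    # root-preferential, moderate elsewhere
    "II_low": (6.0, 0.4),    # root-preferential, low elsewhere
    "III": (7.5, 7.5),
    "IV": (0.4, 4.2),
    "V": (2.4, 2.4),
}
_GROUP_SIZES = {"I": 44, "II_mod": 9, "II_low": 26, "III": 8, "IV": 37, "V": 74}
_N_UNEXPRESSED = 6
_EXPRESSED_MIN_LOG2 = math.log2(1.5) + 0.05   # guarantees TPM >= 0.5 somewhere

#: intron-count pool: 104 intronless, remainder one to ten introns
_INTRON_POOL = ([0] * 104 + [1] * 45 + [2] * 25 + [3] * 14
                + [4, 5, 6, 7, 8, 9, 10] * 2 + [4, 5])


@dataclass
class FixtureManifest:
    """Planted ground truth of the paper-counts fixture (seed-invariant)."""

    master_seed: int
    n_proteins: int
    n_genes: int
    n_splice_variants: int
    tandem_proteins: int
    isolated_proteins: int
    subset_counts: dict[str, int]
    chromosome_counts: dict[int, int]
    chrom_arm_counts: dict[tuple[int, str], int]
    subgenome_counts: dict[str, int]
    long_arm_genes: int
    intron_histogram: dict[int, int]
    intronless_genes: int
    expressed_genes: int
    group_sizes: dict[str, int] = field(default_factory=dict)
    group_genes: dict[str, list[str]] = field(default_factory=dict)
    unexpressed_genes: list[str] = field(default_factory=list)

    def to_flat_dict(self) -> dict[str, object]:
        flat: dict[str, object] = {
            "master_seed": self.master_seed,
            "n_proteins": self.n_proteins,
            "n_genes": self.n_genes,
            "n_splice_variants": self.n_splice_variants,
            "tandem_proteins": self.tandem_proteins,
            "isolated_proteins": self.isolated_proteins,
            "long_arm_genes": self.long_arm_genes,
            "intronless_genes": self.intronless_genes,
            "expressed_genes": self.expressed_genes,
        }
        for subset, n in sorted(self.subset_counts.items()):
            flat[f"subset.{subset}"] = n
        for chrom, n in sorted(self.chromosome_counts.items()):
            flat[f"chromosome.{chrom}"] = n
        for (chrom, arm), n in sorted(self.chrom_arm_counts.items()):
            flat[f"chrom_arm.{chrom}{arm}"] = n
        for sub, n in sorted(self.subgenome_counts.items()):
            flat[f"subgenome.{sub}"] = n
        for k, n in sorted(self.intron_histogram.items()):
            flat[f"introns.{k}"] = n
        for group, n in sorted(self.group_sizes.items()):
            flat[f"expression_group.{group}"] = n
        return flat


@dataclass
class PaperFixture:
    """In-memory paper-counts fixture plus writers for the standard formats."""

    records: list[ProteinRecord]
    truth_domains: dict[str, list[ZFDomain]]
    truth_subsets: dict[str, SubsetAssignment]
    gene_models: list[GeneModel]
    loci: dict[str, GeneLocus]
    tpm: pd.DataFrame
    manifest: FixtureManifest

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteins": outdir / "proteins.fasta",
            "gene_models": outdir / "gene_models.gff3",
            "tpm": outdir / "tpm.tsv",
            "manifest": outdir / "manifest.yaml",
        }
        write_protein_fasta(self.records, paths["proteins"])
        write_gene_models(self.gene_models, paths["gene_models"],
                          seqid_of={g: f"chr{l.chromosome}{l.subgenome}"
                                    for g, l in self.loci.items()})
        self.tpm.to_csv(paths["tpm"], sep="\t", index_label="gene_id")
        import yaml
        paths["manifest"].write_text(
            yaml.safe_dump(self.manifest.to_flat_dict(), sort_keys=True)
        )
        return paths


def _gene_hash(index: int) -> str:
    return hashlib.md5(f"zfsurvey-gene-{index}".encode()).hexdigest()[:9].upper()


def _gene_structure() -> list[dict]:
    """Deterministic (seed-free) structural allocation of the 204 genes."""
    genes: list[dict] = []
    g = 0
    for chrom in sorted(_CHR_TOTALS):
        total, long_quota = _CHR_TOTALS[chrom], _CHR_LONG[chrom]
        for j in range(total):
            perm = (53 * g) % _N_GENES
            sub = "B" if perm < _N_B else ("A" if perm < _N_B + _N_A else "D")
            genes.append({
                "index": g,
                "chromosome": chrom,
                "arm": "L" if j < long_quota else "S",
                "subgenome": sub,
            })
            g += 1

    for gene in genes:
        g = gene["index"]
        gene["n_variants"] = 3 if g < 84 else (2 if g < 169 else 1)
        gene["tandem"] = (g < 50) or (84 <= g < 114) or (169 <= g < 173)

    iso_position = 0
    for gene in genes:
        g = gene["index"]
        if gene["tandem"]:
            gene["arch"] = _TANDEM_ARCHS[g % 2]
            gene["drop_variant"] = None
        else:
            arch = _ISOLATED_ARCHS[iso_position % len(_ISOLATED_ARCHS)]
            gene["arch"] = arch
            # splice-variant series with reduced finger counts: third variant
            # of multi-finger dispersed genes drops the first finger
            gene["drop_variant"] = 3 if (gene["n_variants"] >= 3
                                         and len(arch[0]) >= 3) else None
            iso_position += 1

    for gene, introns in zip(genes, _INTRON_POOL):
        gene["introns"] = introns

    ordered = sorted(range(_N_GENES), key=lambda i: (71 * i) % _N_GENES)
    bounds = {}
    start = 0
    for group in ("I", "II_mod", "II_low", "III", "IV", "V"):
        size = _GROUP_SIZES[group]
        bounds[group] = ordered[start:start + size]
        start += size
    bounds["unexpressed"] = ordered[start:]
    for group, members in bounds.items():
        for i in members:
            genes[i]["expression_group"] = group
    return genes


def paper_counts_fixture(seed: int = 0) -> PaperFixture:
    """Generate the full paper-counts fixture.

    457 proteins over 204 genes (253 extra splice variants), 214 tandem / 243
    isolated proteins, published-style chromosome/arm/sub-genome placement,
    104 intronless gene models, and a TPM matrix in which 198 genes pass the
    default expressed filter and the five planted expression groups are
    recoverable by hierarchical clustering.  All tallies are seed-invariant.
    """
    genes = _gene_structure()
    rng = np.random.default_rng(int(seed) % (2 ** 31 - 1))

    records: list[ProteinRecord] = []
    truth_domains: dict[str, list[ZFDomain]] = {}
    truth_subsets: dict[str, SubsetAssignment] = {}
    loci: dict[str, GeneLocus] = {}
    gene_models: list[GeneModel] = []

    for gene in genes:
        locus = GeneLocus(chromosome=gene["chromosome"], subgenome=gene["subgenome"],
                          arm=gene["arm"], hash=_gene_hash(gene["index"]))
        gene_id = compose_gene_id(locus)
        gene["gene_id"] = gene_id
        loci[gene_id] = locus

        types, gaps = gene["arch"]
        for v in range(1, gene["n_variants"] + 1):
            if gene["drop_variant"] == v:
                v_types, v_gaps = types[1:], gaps[1:]
            else:
                v_types, v_gaps = types, gaps
            protein_id = f"{gene_id}.{v}"
            child_seed = int((int(seed) * 1000003 + gene["index"] * 131 + v)
                             % (2 ** 31 - 1))
            spec = ProteinSpec(
                protein_id=protein_id, domain_types=tuple(v_types),
                gaps=tuple(v_gaps), n_flank=12, c_flank=12, seed=child_seed,
            )
            record, domains, _ = make_protein(spec)
            records.append(record)
            truth_domains[protein_id] = domains
            truth_subsets[protein_id] = assign_subset(build_architecture(domains))

        # gene model: fixed exon/intron geometry from the planted intron count
        n_exons = gene["introns"] + 1
        exons = []
        pos = 100
        for _ in range(n_exons):
            exons.append((pos, pos + 120))
            pos += 120 + 90
        gene_models.append(GeneModel(gene_id=gene_id, mrna_id=f"{gene_id}.1",
                                     exons=tuple(exons)))

    # expression matrix
    samples = list(STAGE_CODES)
    tpm_rows: dict[str, np.ndarray] = {}
    for gene in genes:
        group = gene["expression_group"]
        if group == "unexpressed":
            tpm_rows[gene["gene_id"]] = rng.uniform(0.0, 0.1, size=15)
            continue
        root_level, other_level = _GROUP_PROFILES[group]
        profile = np.array([root_level] * 3 + [other_level] * 12)
        logvals = profile + rng.normal(0.0, 0.3, size=15)
        if logvals.max() < _EXPRESSED_MIN_LOG2:
            logvals[int(np.argmax(logvals))] = _EXPRESSED_MIN_LOG2
        tpm_rows[gene["gene_id"]] = np.clip(2.0 ** logvals - 1.0, 0.0, None)
    tpm = pd.DataFrame.from_dict(tpm_rows, orient="index", columns=samples)
    tpm = tpm.loc[[g["gene_id"] for g in genes]]

    # manifest from planted truth
    tandem_proteins = sum(1 for a in truth_subsets.values() if a.arrangement == "tandem")
    subset_counts: dict[str, int] = {}
    for a in truth_subsets.values():
        subset_counts[a.subset] = subset_counts.get(a.subset, 0) + 1
    chrom_counts: dict[int, int] = {}
    chrom_arm: dict[tuple[int, str], int] = {}
    sub_counts: dict[str, int] = {}
    for gene in genes:
        chrom_counts[gene["chromosome"]] = chrom_counts.get(gene["chromosome"], 0) + 1
        chrom_arm[(gene["chromosome"], gene["arm"])] = (
            chrom_arm.get((gene["chromosome"], gene["arm"]), 0) + 1
        )
        sub_counts[gene["subgenome"]] = sub_counts.get(gene["subgenome"], 0) + 1
    intron_hist: dict[int, int] = {}
    for gene in genes:
        intron_hist[gene["introns"]] = intron_hist.get(gene["introns"], 0) + 1

    group_sizes = dict(_GROUP_SIZES)
    group_sizes["II"] = _GROUP_SIZES["II_mod"] + _GROUP_SIZES["II_low"]
    group_genes = {
        group: [g["gene_id"] for g in genes if g["expression_group"] == group]
        for group in _GROUP_SIZES
    }
    group_genes["II"] = group_genes["II_mod"] + group_genes["II_low"]

    manifest = FixtureManifest(
        master_seed=int(seed),
        n_proteins=len(records),
        n_genes=len(genes),
        n_splice_variants=len(records) - len(genes),
        tandem_proteins=tandem_proteins,
        isolated_proteins=len(records) - tandem_proteins,
        subset_counts=subset_counts,
        chromosome_counts=chrom_counts,
        chrom_arm_counts=chrom_arm,
        subgenome_counts=sub_counts,
        long_arm_genes=sum(n for (c, a), n in chrom_arm.items() if a == "L"),
        intron_histogram=intron_hist,
        intronless_genes=intron_hist.get(0, 0),
        expressed_genes=_N_GENES - _N_UNEXPRESSED,
        group_sizes=group_sizes,
        group_genes=group_genes,
        unexpressed_genes=[g["gene_id"] for g in genes
                           if g["expression_group"] == "unexpressed"],
    )
    return PaperFixture(
        records=records, truth_domains=truth_domains, truth_subsets=truth_subsets,
        gene_models=gene_models, loci=loci, tpm=tpm, manifest=manifest,
    )
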