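"""Nei-Gojobori (NG86) Ka/Ks with Jukes-Cantor correction and clock dating.

Synonymous (S) and nonsynonymous (N) *site* counts: each codon position
contributes the fraction of its three possible single-nucleotide changes that
preserve the encoded amino acid; changes into stop codons count as
nonsynonymous.  *Difference* counts (Sd, Nd) between two codons average the
synonymous/nonsynonymous composition over every minimal mutational pathway
(1, 2 or 6 orderings), excluding pathways that pass through a stop codon.
Proportions ps = Sd / S and pn = Nd / N (sites averaged over the two
sequences) are corrected with the Jukes-Cantor formula
K = -(3/4) ln(1 - (4/3) p); omega = Ka/Ks classifies selection (<1 purifying,
~1 neutral, >1 positive).  Divergence time follows the molecular clock
T = Ks / (2 lambda x 1e6) Mya with the grass-clade rate
lambda = 6.5e-9 substitutions per synonymous site per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio.Data import CodonTable

from zfsurvey.errors import CodonError

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
)
BASES = "ACGT"

#: default synonymous substitution rate per site per year (grass clade)
DEFAULT_LAMBDA = 6.5e-9

#: Jukes-Cantor saturation threshold: p >= 3/4 has no finite correction
SATURATION = 0.75


def _check_codon(codon: str) -> str:
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise CodonError(f"invalid codon {codon!r}")
    return codon


def _split_codons(cds: str) -> list[str]:
    if len(cds) % 3 != 0:
        raise CodonError(f"CDS length {len(cds)} is not a multiple of 3")
    return [cds[i:i + 3] for i in range(0, len(cds), 3)]


@dataclass(frozen=True)
class CodonPair:
    """Two aligned, gap-free, equal-length coding sequences."""

    id_a: str
    id_b: str
    cds_a: str
    cds_b: str

    @classmethod
    def from_aligned(cls, id_a: str, id_b: str, seq_a: str, seq_b: str) -> "CodonPair":
        """Build a pair from an aligned CDS pair, dropping gapped codon columns.

        Sequences must be equal length and a multiple of 3; codon columns in
        which either sequence carries ``-`` are removed.  A shared terminal
        stop codon is stripped; internal stops are errors.
        """
        a, b = seq_a.upper().replace("U", "T"), seq_b.upper().replace("U", "T")
        if len(a) != len(b):
            raise CodonError(
                f"aligned sequences differ in length ({len(a)} vs {len(b)})"
            )
        cods_a, cods_b = _split_codons(a), _split_codons(b)
        kept_a, kept_b = [], []
        for ca, cb in zip(cods_a, cods_b):
            if "-" in ca or "-" in cb:
                continue
            kept_a.append(_check_codon(ca))
            kept_b.append(_check_codon(cb))
        if kept_a and CODON_TO_AA[kept_a[-1]] == "*" and CODON_TO_AA[kept_b[-1]] == "*":
            kept_a.pop()
            kept_b.pop()
        if len(kept_a) < 1:
            raise CodonError("no ungapped codons remain in the alignment")
        for cods, name in ((kept_a, id_a), (kept_b, id_b)):
            stops = [i for i, c in enumerate(cods) if CODON_TO_AA[c] == "*"]
            if stops:
                raise CodonError(f"{name}: internal stop codon at codon {stops[0] + 1}")
        return cls(id_a=id_a, id_b=id_b, cds_a="".join(kept_a), cds_b="".join(kept_b))


@dataclass(frozen=True)
class KaKsResult:
    id_a: str
    id_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ka: Optional[float]
    Ks: Optional[float]
    omega: Optional[float]
    selection: Optional[str]   # purifying | neutral | positive
    T_mya: Optional[float]
    saturated: bool


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    aa = CODON_TO_AA[codon]
    if aa == "*":
        raise CodonError(f"stop codon {codon!r} has no site decomposition")
    syn = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if CODON_TO_AA[mutant] == aa:   # stop mutants are nonsynonymous
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def count_sites(cds: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts of a codon string (NG86).

    Additive per codon; S + N equals the nucleotide length.  An internal stop
    codon is an error (a single terminal stop is tolerated and skipped).
    """
    codons = [_check_codon(c) for c in _split_codons(cds.upper().replace("U", "T"))]
    if codons and CODON_TO_AA[codons[-1]] == "*":
        codons = codons[:-1]
    stops = [i for i, c in enumerate(codons) if CODON_TO_AA[c] == "*"]
    if stops:
        raise CodonError(f"internal stop codon at codon {stops[0] + 1}")
    S = N = 0.0
    for c in codons:
        s, n = _codon_sites(c)
        S += s
        N += n
    return S, N


@lru_cache(maxsize=None)
def _codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) between two sense codons.

    Minimal pathways change one differing position at a time; pathways through
    a stop codon are excluded.  If every ordering is blocked by stops, the raw
    differences are counted as nonsynonymous.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    valid = 0
    for order in permutations(diff):
        cur = codon_a
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if CODON_TO_AA[nxt] == "*":
                blocked = True
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if not blocked:
            syn_total += syn
            nonsyn_total += nonsyn
            valid += 1
    if valid == 0:
        return 0.0, float(len(diff))
    return syn_total / valid, nonsyn_total / valid


def count_differences(pair: CodonPair) -> tuple[float, float]:
    """Total pathway-averaged synonymous/nonsynonymous differences of a pair."""
    Sd = Nd = 0.0
    for ca, cb in zip(_split_codons(pair.cds_a), _split_codons(pair.cds_b)):
        s, n = _codon_differences(ca, cb)
        Sd += s
        Nd += n
    return Sd, Nd


def _jukes_cantor(p: float) -> Optional[float]:
    if p >= SATURATION:
        return None
    return -0.75 * math.log(1.0 - p / 0.75) + 0.0


def kaks(pair: CodonPair, neutral_band: float = 0.05,
         lam: float = DEFAULT_LAMBDA) -> KaKsResult:
    """NG86 Ka/Ks of an aligned codon pair with selection call and clock date.

    Site counts are averaged over the two sequences.  When ps or pn reaches
    the Jukes-Cantor saturation bound 3/4 the corresponding rate (and any
    quantity derived from it) is reported as None and the result flagged
    ``saturated``; no exception is raised.  omega = 1 is approximated by the
    configurable neutrality band |omega - 1| <= ``neutral_band``.
    """
    S_a, N_a = count_sites(pair.cds_a)
    S_b, N_b = count_sites(pair.cds_b)
    S, N = (S_a + S_b) / 2.0, (N_a + N_b) / 2.0
    Sd, Nd = count_differences(pair)
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(ps)
    Ka = _jukes_cantor(pn)
    saturated = Ks is None or Ka is None

    omega: Optional[float] = None
    selection: Optional[str] = None
    if Ka is not None and Ks is not None:
        if Ks > 0:
            omega = Ka / Ks
        elif Ka > 0:
            omega = math.inf
        if omega is not None:
            if abs(omega - 1.0) <= neutral_band:
                selection = "neutral"
            elif omega > 1.0:
                selection = "positive"
            else:
                selection = "purifying"
    T = divergence_time(Ks, lam) if Ks is not None else None
    return KaKsResult(
        id_a=pair.id_a, id_b=pair.id_b, S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn,
        Ka=Ka, Ks=Ks, omega=omega, selection=selection, T_mya=T,
        saturated=saturated,
    )


def divergence_time(ks: float, lam: float = DEFAULT_LAMBDA) -> float:
    """Molecular-clock date in Mya: T = Ks / (2 lambda x 1e6)."""
    if ks < 0:
        raise CodonError(f"Ks must be non-negative, got {ks}")
    return ks / (2.0 * lam * 1e6)


def read_codon_pairs(path: str | Path) -> list[CodonPair]:
    """Read aligned CDS pairs from FASTA (consecutive record pairs) or 4-column TSV."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        from Bio import SeqIO
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) % 2 != 0:
            raise CodonError(f"{path}: paired FASTA must hold an even record count")
        return [
            CodonPair.from_aligned(a.id, b.id, str(a.seq), str(b.seq))
            for a, b in zip(records[::2], records[1::2])
        ]
    pairs = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("id_a\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise CodonError(f"{path}: expected 4 tab-separated columns, got {line!r}")
        pairs.append(CodonPair.from_aligned(*parts))
    return pairs


def kaks_table(pairs: list[CodonPair], neutral_band: float = 0.05,
               lam: float = DEFAULT_LAMBDA) -> pd.DataFrame:
    rows = []
    for pair in pairs:
        r = kaks(pair, neutral_band=neutral_band, lam=lam)
        rows.append({
            "id_a": r.id_a, "id_b": r.id_b, "S": r.S, "N": r.N,
            "Sd": r.Sd, "Nd": r.Nd, "Ka": r.Ka, "Ks": r.Ks,
            "omega": r.omega, "selection": r.selection, "T_mya": r.T_mya,
            "saturated": r.saturated,
        })
    return pd.DataFrame(
        rows, columns=["id_a", "id_b", "S", "N", "Sd", "Nd", "Ka", "Ks",
                       "omega", "selection", "T_mya", "saturated"]
    )
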