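"""C2H2 zinc-finger detection and typing.

A C2H2 finger coordinates one Zn2+ through two cysteines and (usually) two
histidines, with the plant consensus C-X2-4-C-X3-F-X5-L-X2-H-X3-5-H.  Plant
fingers carry the invariant hexapeptide QALGGH whose terminal H is the first
zinc-ligand histidine; finger types are read off the integrity of that window:

* ``Q``   — intact QALGGH and a Cys2->His1 spacing of exactly 12 residues,
* ``M1``-``M4`` — k substitutions among the first five QALGGH residues,
* ``Z1``/``Z2`` — fully degenerate window, split by spacing >= 12 vs < 12,
* ``D``   — the second histidine ligand is missing.

Detection is a deterministic two-pass greedy scan; it is intentionally simple
enough to be checked against exhaustive ligand-quadruple enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import pandas as pd

from zfsurvey.sequence_io import ProteinRecord

QALGGH = "QALGGH"


@dataclass(frozen=True)
class ScanParams:
    """Bounds of the finger consensus and typing knobs.

    ``cc_gap_*``: residues strictly between the two cysteines (consensus 2-4).
    ``spacing_*``: residues strictly between Cys2 and His1; the plant Q-type
    pattern X2-C-X2-C-X7-QALGGH-X3-H fixes this at 12, degenerate fingers roam.
    ``hh_gap_*``: residues strictly between the histidines (consensus 3-5).
    ``require_FL``: enforce the F and L of the general consensus at Cys2+4 and
    Cys2+10 (off by default; the Q-type pattern itself omits them).
    ``m_max_mismatch``: largest QALGGH substitution count still typed M.
    ``five_mismatch_to_z``: route a fully substituted (5/5) window to Z.
    ``d_tail_max``: residues after Cys2 searched for the lone His of a D call.
    """

    cc_gap_min: int = 2
    cc_gap_max: int = 4
    spacing_min: int = 7
    spacing_max: int = 30
    hh_gap_min: int = 3
    hh_gap_max: int = 5
    require_FL: bool = False
    m_max_mismatch: int = 4
    five_mismatch_to_z: bool = True
    d_tail_max: int = 30

    def __post_init__(self) -> None:
        for name in ("cc_gap_min", "cc_gap_max", "spacing_min", "spacing_max",
                     "hh_gap_min", "hh_gap_max", "m_max_mismatch", "d_tail_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.spacing_min <= 12 <= self.spacing_max):
            raise ValueError("spacing bounds must bracket the canonical spacing 12")


@dataclass(frozen=True)
class ZFDomain:
    """One detected finger; positions 0-based, span half-open [start, end)."""

    protein_id: str
    c1: int
    c2: int
    h1: int
    h2: Optional[int]       # None for D-type (no second histidine ligand)
    start: int
    end: int
    spacing: int            # residues strictly between c2 and h1
    window: str             # 6-residue string ending at h1 (the QALGGH slot)
    mismatches: int         # Hamming distance of window to QALGGH
    ztype_spacing_rule: int # spacing threshold used for the Z1/Z2 split
    dtype: str              # Q, M1..M4, Z1, Z2, D


def _window(sequence: str, h1: int) -> str:
    return sequence[h1 - 5: h1 + 1]


def _mismatches(window: str) -> int:
    return sum(1 for a, b in zip(window, QALGGH) if a != b)


def classify_domain(domain: ZFDomain, params: ScanParams = ScanParams()) -> str:
    """Assign the finger type by the decision cascade.

    1. no second histidine -> D;
    2. intact QALGGH with spacing 12 -> Q;
    3. 1..m_max_mismatch substitutions in the first five window residues -> M_k;
    4. otherwise Z1 (spacing >= 12) or Z2 (spacing < 12).
    """
    if domain.h2 is None:
        return "D"
    if domain.window == QALGGH and domain.spacing == 12:
        return "Q"
    k = domain.mismatches
    if 1 <= k <= params.m_max_mismatch and not (k == 5 and params.five_mismatch_to_z):
        return f"M{k}"
    return "Z1" if domain.spacing >= 12 else "Z2"


def _full_candidates(seq: str, params: ScanParams) -> list[tuple[int, int, int, int]]:
    """All (c1, c2, h1, h2) quadruples satisfying the scan bounds, sorted."""
    n = len(seq)
    out: list[tuple[int, int, int, int]] = []
    for c1 in range(n):
        if seq[c1] != "C":
            continue
        for cc_gap in range(params.cc_gap_min, params.cc_gap_max + 1):
            c2 = c1 + cc_gap + 1
            if c2 >= n or seq[c2] != "C":
                continue
            if params.require_FL:
                if c2 + 10 >= n or seq[c2 + 4] != "F" or seq[c2 + 10] != "L":
                    continue
            for spacing in range(params.spacing_min, params.spacing_max + 1):
                h1 = c2 + spacing + 1
                if h1 >= n or seq[h1] != "H":
                    continue
                for hh_gap in range(params.hh_gap_min, params.hh_gap_max + 1):
                    h2 = h1 + hh_gap + 1
                    if h2 >= n or seq[h2] != "H":
                        continue
                    out.append((c1, c2, h1, h2))
    return out


def scan_domains(record: ProteinRecord,
                 params: ScanParams = ScanParams()) -> list[ZFDomain]:
    """Detect all non-overlapping fingers, leftmost-first, and type them.

    Pass 1 places full C..C..H..H units greedily: candidate quadruples are
    ordered lexicographically by (c1, c2, h1, h2) and accepted whenever their
    span does not overlap an accepted span.  Pass 2 revisits residues not
    covered by pass 1 and emits D-type fingers: a C..C pair followed by exactly
    one histidine (the QALGGH-terminal one) within ``d_tail_max`` residues of
    Cys2; the tail inspection stops at the first pass-1-covered residue.
    ``X`` never matches a ligand position.  Domains never share a residue.
    """
    seq = record.sequence
    domains: list[ZFDomain] = []
    covered = [False] * len(seq)

    def is_free(a: int, b: int) -> bool:
        return not any(covered[a:b])

    def mark(a: int, b: int) -> None:
        for i in range(a, b):
            covered[i] = True

    for c1, c2, h1, h2 in _full_candidates(seq, params):
        if not is_free(c1, h2 + 1):
            continue
        window = _window(seq, h1)
        dom = ZFDomain(
            protein_id=record.id, c1=c1, c2=c2, h1=h1, h2=h2,
            start=c1, end=h2 + 1, spacing=h1 - c2 - 1, window=window,
            mismatches=_mismatches(window), ztype_spacing_rule=12, dtype="",
        )
        dom = replace(dom, dtype=classify_domain(dom, params))
        domains.append(dom)
        mark(c1, h2 + 1)

    # pass 2: D-type (single-histidine) fingers on uncovered sequence
    n = len(seq)
    for c1 in range(n):
        if seq[c1] != "C" or covered[c1]:
            continue
        for cc_gap in range(params.cc_gap_min, params.cc_gap_max + 1):
            c2 = c1 + cc_gap + 1
            if c2 >= n or seq[c2] != "C" or not is_free(c1, c2 + 1):
                continue
            his: list[int] = []
            for t in range(c2 + 1, min(n, c2 + params.d_tail_max + 1)):
                if covered[t]:
                    break
                if seq[t] == "H":
                    his.append(t)
            if len(his) != 1:
                continue
            h1 = his[0]
            spacing = h1 - c2 - 1
            if not (params.spacing_min <= spacing <= params.spacing_max):
                continue
            if h1 < 5 or not is_free(c1, h1 + 1):
                continue
            window = _window(seq, h1)
            dom = ZFDomain(
                protein_id=record.id, c1=c1, c2=c2, h1=h1, h2=None,
                start=c1, end=h1 + 1, spacing=spacing, window=window,
                mismatches=_mismatches(window), ztype_spacing_rule=12, dtype="D",
            )
            domains.append(dom)
            mark(c1, h1 + 1)
            break  # one finger per c1

    domains.sort(key=lambda d: d.start)
    return domains


def domains_to_table(domains: list[ZFDomain]) -> pd.DataFrame:
    """Per-domain report table; start/end and ligand positions 1-based inclusive."""
    rows = [
        {
            "protein_id": d.protein_id,
            "start": d.start + 1,
            "end": d.end,
            "c1": d.c1 + 1,
            "c2": d.c2 + 1,
            "h1": d.h1 + 1,
            "h2": d.h2 + 1 if d.h2 is not None else "",
            "spacing": d.spacing,
            "window": d.window,
            "mismatches": d.mismatches,
            "dtype": d.dtype,
        }
        for d in domains
    ]
    return pd.DataFrame(
        rows,
        columns=["protein_id", "start", "end", "c1", "c2", "h1", "h2",
                 "spacing", "window", "mismatches", "dtype"],
    )
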