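"""Independent brute-force oracles used by the test suite.

These deliberately re-derive the package's core quantities from first
principles (exhaustive enumeration, recursive pathway averaging) so that the
implementation and its checks share no code path.
"""

from __future__ import annotations

from itertools import permutations

from Bio.Data import CodonTable

# ---------------------------------------------------------------------------
# zinc-finger scanner oracle

_T = CodonTable.unambiguous_dna_by_id[1]
_AA = dict(_T.forward_table)
for _s in _T.stop_codons:
    _AA[_s] = "*"


def oracle_scan(seq: str, params) -> list[tuple[int, int, int, int | None]]:
    """Exhaustive-enumeration scanner: returns (c1, c2, h1, h2) tuples.

    Pass 1: enumerate every full ligand quadruple satisfying the bounds, keep
    the lexicographically leftmost non-overlapping set.  Pass 2: on residues
    not covered by pass 1, C..C pairs followed by exactly one histidine in the
    tail window (scan stopping at covered residues) become D-type units.
    """
    n = len(seq)
    cs = [i for i, ch in enumerate(seq) if ch == "C"]
    hs = [i for i, ch in enumerate(seq) if ch == "H"]
    quads = []
    for c1 in cs:
        for c2 in cs:
            if not (params.cc_gap_min <= c2 - c1 - 1 <= params.cc_gap_max):
                continue
            if params.require_FL:
                if c2 + 10 >= n or seq[c2 + 4] != "F" or seq[c2 + 10] != "L":
                    continue
            for h1 in hs:
                if not (params.spacing_min <= h1 - c2 - 1 <= params.spacing_max):
                    continue
                for h2 in hs:
                    if not (params.hh_gap_min <= h2 - h1 - 1 <= params.hh_gap_max):
                        continue
                    quads.append((c1, c2, h1, h2))
    quads.sort()
    covered = set()
    chosen: list[tuple[int, int, int, int | None]] = []
    for c1, c2, h1, h2 in quads:
        span = set(range(c1, h2 + 1))
        if span & covered:
            continue
        chosen.append((c1, c2, h1, h2))
        covered |= span

    for c1 in cs:
        if c1 in covered:
            continue
        done = False
        for c2 in cs:
            if done or not (params.cc_gap_min <= c2 - c1 - 1 <= params.cc_gap_max):
                continue
            if any(p in covered for p in range(c1, c2 + 1)):
                continue
            tail_hs = []
            for t in range(c2 + 1, min(n, c2 + params.d_tail_max + 1)):
                if t in covered:
                    break
                if seq[t] == "H":
                    tail_hs.append(t)
            if len(tail_hs) != 1:
                continue
            h1 = tail_hs[0]
            if not (params.spacing_min <= h1 - c2 - 1 <= params.spacing_max):
                continue
            if h1 < 5 or any(p in covered for p in range(c1, h1 + 1)):
                continue
            chosen.append((c1, c2, h1, None))
            covered |= set(range(c1, h1 + 1))
            done = True
    chosen.sort()
    return chosen


# ---------------------------------------------------------------------------
# NG86 oracle


def oracle_sites(codon: str) -> tuple[float, float]:
    """Fraction of the nine single-base mutants that are synonymous."""
    syn = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if _AA[mut] == _AA[codon]:
                syn += 1 / 3
    return syn, 3 - syn


def oracle_codon_diffs(a: str, b: str) -> tuple[float, float]:
    """Average syn/nonsyn steps over all stop-free orderings of the changes."""
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    results = []
    for order in permutations(positions):
        cur, syn, non, ok = a, 0, 0, True
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1:]
            if _AA[nxt] == "*":
                ok = False
                break
            if _AA[nxt] == _AA[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            results.append((syn, non))
    if not results:
        return 0.0, float(len(positions))
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))
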