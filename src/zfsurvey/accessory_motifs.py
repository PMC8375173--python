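"""Accessory (non-zinc-finger) box matching and positional context.

Plant C2H2-ZF proteins carry short functional boxes outside the fingers —
most prominently the EAR repression motif (DLNxxP or LxLxL) and EAR-like
variants (LDLNL, LDLSL, FDLNI) — plus subset-specific boxes (L-, EK-, PL-,
R-, NPL-, SFP1-box) whose consensus is known only from sequence logos and is
therefore shipped pattern-less: users supply a pattern via configuration.

Patterns are degenerate amino-acid expressions where ``x`` matches any
residue; matching is exact and position-based, no scoring.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from zfsurvey.errors import ZfSurveyError
from zfsurvey.sequence_io import ProteinRecord
from zfsurvey.zf_scan import ZFDomain

#: declared-context vocabulary
CONTEXTS = (
    "N-of-first-ZF", "C-of-first-ZF", "C-of-second-ZF", "C-of-last-ZF", "anywhere",
)


@dataclass(frozen=True)
class MotifPattern:
    """A named box: degenerate pattern (or None for logo-only boxes) + context."""

    name: str
    pattern: Optional[str]
    context: str = "anywhere"

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ZfSurveyError(f"unknown context {self.context!r} for {self.name}")
        if self.pattern is not None:
            if len(self.pattern) < 3:
                raise ZfSurveyError(f"pattern for {self.name} shorter than 3 residues")
            if not re.fullmatch(r"[A-Zx]+", self.pattern):
                raise ZfSurveyError(
                    f"pattern for {self.name} may contain only uppercase letters and x"
                )

    def regex(self) -> "re.Pattern[str]":
        assert self.pattern is not None
        return re.compile("".join("." if ch == "x" else ch for ch in self.pattern))


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    name: str
    start: int               # 0-based half-open span
    end: int
    matched_text: str
    context_observed: str
    context_ok: bool


def default_library() -> list[MotifPattern]:
    """The shipped box library.

    Concrete patterns: the EAR motif (DLNxxP, LxLxL) and EAR-like variants
    (LDLNL, LDLSL, FDLNI).  Logo-only boxes carry their declared location but
    no pattern; :func:`find_boxes` skips them until a pattern is supplied.
    """
    return [
        MotifPattern("EAR-DLNxxP", "DLNxxP", "anywhere"),
        MotifPattern("EAR-LxLxL", "LxLxL", "anywhere"),
        MotifPattern("EAR-LDLNL", "LDLNL", "anywhere"),
        MotifPattern("EAR-LDLSL", "LDLSL", "anywhere"),
        MotifPattern("EAR-FDLNI", "FDLNI", "anywhere"),
        MotifPattern("L-box", None, "N-of-first-ZF"),
        MotifPattern("NPL-box", None, "N-of-first-ZF"),
        MotifPattern("DL-box", None, "C-of-last-ZF"),
        MotifPattern("R-box", None, "C-of-first-ZF"),
        MotifPattern("SFP1-box", None, "C-of-first-ZF"),
        MotifPattern("PL-box", None, "C-of-second-ZF"),
        MotifPattern("EK-box", None, "C-of-second-ZF"),
    ]


def read_library(path: str | Path) -> list[MotifPattern]:
    """Read a box library from a 2-3 column TSV: name, pattern[, context].

    A ``-`` or empty pattern field declares a logo-only box.
    """
    patterns = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        name = parts[0]
        pattern = parts[1] if len(parts) > 1 and parts[1] not in ("", "-") else None
        context = parts[2] if len(parts) > 2 and parts[2] else "anywhere"
        patterns.append(MotifPattern(name, pattern, context))
    return patterns


def _observed_context(start: int, end: int, domains: Sequence[ZFDomain]) -> str:
    if not domains:
        return "anywhere"
    if any(start < d.end and end > d.start for d in domains):
        return "within-ZF"
    if end <= domains[0].start:
        return "N-of-first-ZF"
    ordinal = {0: "first", 1: "second", 2: "third", 3: "fourth"}
    for k, d in enumerate(domains):
        after_k = start >= d.end
        before_next = k + 1 >= len(domains) or end <= domains[k + 1].start
        if after_k and before_next:
            if k == 0:
                return "C-of-first-ZF"
            if k == len(domains) - 1:
                return "C-of-last-ZF"
            return f"C-of-{ordinal.get(k, str(k + 1) + 'th')}-ZF"
    return "anywhere"


def _context_satisfied(declared: str, start: int, end: int,
                       domains: Sequence[ZFDomain]) -> bool:
    if declared == "anywhere":
        return True
    if not domains:
        return False
    if declared == "N-of-first-ZF":
        return end <= domains[0].start
    if declared == "C-of-first-ZF":
        return (start >= domains[0].end
                and (len(domains) == 1 or end <= domains[1].start))
    if declared == "C-of-second-ZF":
        return (len(domains) >= 2 and start >= domains[1].end
                and (len(domains) == 2 or end <= domains[2].start))
    if declared == "C-of-last-ZF":
        return start >= domains[-1].end
    return False


def find_boxes(
    record: ProteinRecord,
    domains: Sequence[ZFDomain],
    library: Optional[Iterable[MotifPattern]] = None,
) -> list[MotifHit]:
    """Report every leftmost non-overlapping match of every concrete pattern.

    Overlapping matches of *different* patterns are all reported; within one
    pattern, matches are the leftmost non-overlapping set.  The observed
    context is computed from the hit span relative to the finger spans
    (a 0-residue gap still counts as outside a finger); ``context_ok`` states
    whether the declared context of the pattern is satisfied.
    """
    domains = sorted(domains, key=lambda d: d.start)
    hits: list[MotifHit] = []
    for pat in (library if library is not None else default_library()):
        if pat.pattern is None:
            continue
        for m in pat.regex().finditer(record.sequence):
            start, end = m.start(), m.end()
            observed = _observed_context(start, end, domains)
            hits.append(MotifHit(
                protein_id=record.id,
                name=pat.name,
                start=start,
                end=end,
                matched_text=m.group(0),
                context_observed=observed,
                context_ok=_context_satisfied(pat.context, start, end, domains),
            ))
    hits.sort(key=lambda h: (h.start, h.name))
    return hits


def hits_to_table(hits: Sequence[MotifHit]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": h.protein_id,
            "box": h.name,
            "start": h.start + 1,
            "end": h.end,
            "matched_text": h.matched_text,
            "context_observed": h.context_observed,
            "context_ok": h.context_ok,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows, columns=["protein_id", "box", "start", "end", "matched_text",
                       "context_observed", "context_ok"]
    )
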