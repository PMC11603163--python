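"""Diagnostic-motif detection and motif-based subunit classification.

The three vascular-plant polymerase families carry distinctive sequence
signatures in their largest subunits:

* Pol II (NRPB1): tandem YSPTSPS-type heptad repeats in the C-terminal
  domain (CTD);
* Pol V (NRPE1): repeated GW/WG AGO-hook motifs in the CTD;
* Pol IV (NRPD1): the bipartite CYC-YPxF motif in the clamp head (two
  zinc-coordinating cysteines followed, after a short spacer, by YPxF).

Bryophyte NRPD1/NRPE1-like subunits form a fourth cluster: they combine a
GW/WG-rich CTD with a shortened CYC-YP motif that lacks the YPxF part.

Patterns use a PROSITE-like dialect: elements separated by ``-``, each a
literal letter (or run of letters), an ``x`` wildcard, or a bracketed
alternative ``[TS]``, optionally carrying a bounded repeat ``(n)`` or
``(n,m)``.  Example: ``C-Y-x(0,1)-C``.

All scanners are deterministic; matches are reported non-overlapping,
leftmost-first, taking the longest match at each anchor position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional

from .seqio_filter import AA20, ProteinRecord

# Motif class labels.
HEPTAD = "HEPTAD"
GWWG = "GWWG"
CYC_YPXF = "CYC_YPXF"
CYC_YP_PARTIAL = "CYC_YP_PARTIAL"
METAL_A = "METAL_A"

# Classification labels.
B1_LIKE = "B1_like"
D1_LIKE = "D1_like"
E1_LIKE = "E1_like"
DE_LIKE = "DE_like"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; coordinates 1-based inclusive."""

    motif_class: str
    start: int
    end: int
    matched_text: str
    score: float = 1.0

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid hit span ({self.start}, {self.end})")
        if len(self.matched_text) != self.end - self.start + 1:
            raise ValueError("matched_text length does not equal the hit span")


@dataclass(frozen=True)
class ClassificationCall:
    """Motif-based family assignment for one record."""

    record_id: str
    label: str
    evidence: Mapping[str, float]
    rule_fired: str


@dataclass(frozen=True)
class MotifConfig:
    """Tunable motif definitions and thresholds.

    Defaults: the canonical Pol II CTD heptad consensus Y-S-P-[TS]-S-P-S with
    up to 2 mismatches per heptad and at least 5 tandem repeats; the CTD
    search window is the C-terminal 40% of the sequence; "repeated" GW/WG
    means at least 5 non-overlapping occurrences; the CYC sub-motif is
    C-Y-x(0,1)-C (one optional position between the tyrosine and the second
    cysteine, accommodating both a 3- and a 4-residue reading), followed
    within 20 residues by Y-P-x-F.
    """

    heptad_consensus: str = "Y-S-P-[TS]-S-P-S"
    heptad_max_mismatch: int = 2
    heptad_min_repeats: int = 5
    ctd_fraction: float = 0.4
    gwwg_min_count: int = 5
    cyc_pattern: str = "C-Y-x(0,1)-C"
    ypxf_pattern: str = "Y-P-x-F"
    cyc_ypxf_max_spacer: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.ctd_fraction <= 1.0):
            raise ValueError("ctd_fraction must be in (0, 1]")
        for name in (
            "heptad_max_mismatch",
            "heptad_min_repeats",
            "gwwg_min_count",
            "cyc_ypxf_max_spacer",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class PatternError(ValueError):
    """Malformed motif pattern; carries the position of the syntax fault."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at pattern position {position})")
        self.position = position


@dataclass(frozen=True)
class _Element:
    """One pattern element: an allowed-residue set (None = wildcard) with a
    bounded repeat count."""

    allowed: Optional[frozenset]
    min_rep: int = 1
    max_rep: int = 1


_TOKEN_RE = re.compile(
    r"(?P<body>x|\[[A-Z]+\]|[A-Z]+)(?:\((?P<lo>\d+)(?:,(?P<hi>\d+))?\))?$"
)


def parse_pattern(pattern: str) -> list[_Element]:
    """Parse a PROSITE-like pattern into elements; errors carry the position
    of the first offending character."""
    if not pattern:
        raise PatternError("empty pattern", 0)
    elements: list[_Element] = []
    offset = 0
    for token in pattern.split("-"):
        if not token:
            raise PatternError("empty pattern element", offset)
        m = _TOKEN_RE.match(token)
        if m is None:
            raise PatternError(f"malformed element {token!r}", offset)
        body = m.group("body")
        lo = m.group("lo")
        hi = m.group("hi")
        min_rep, max_rep = 1, 1
        if lo is not None:
            min_rep = int(lo)
            max_rep = int(hi) if hi is not None else min_rep
            if max_rep < min_rep:
                raise PatternError("repeat upper bound below lower bound", offset)
        if body == "x":
            allowed = None
        elif body.startswith("["):
            inner = body[1:-1]
            bad = set(inner) - set(AA20)
            if bad:
                raise PatternError(f"invalid residues {sorted(bad)} in class", offset)
            allowed = frozenset(inner)
        else:
            bad = set(body) - set(AA20)
            if bad:
                raise PatternError(f"invalid literal residues {sorted(bad)}", offset)
            if len(body) > 1:
                if lo is not None:
                    raise PatternError(
                        "repeat applied to a multi-letter literal", offset
                    )
                elements.extend(_Element(frozenset(ch)) for ch in body)
                offset += len(token) + 1
                continue
            allowed = frozenset(body)
        elements.append(_Element(allowed, min_rep, max_rep))
        offset += len(token) + 1
    return elements


def _elements_to_regex(elements: list[_Element]) -> "re.Pattern[str]":
    parts = []
    for el in elements:
        if el.allowed is None:
            atom = "."
        elif len(el.allowed) == 1:
            atom = next(iter(el.allowed))
        else:
            atom = "[" + "".join(sorted(el.allowed)) + "]"
        if (el.min_rep, el.max_rep) != (1, 1):
            atom += f"{{{el.min_rep},{el.max_rep}}}"
        parts.append(atom)
    return re.compile("".join(parts))


def _span_bounds(elements: list[_Element]) -> tuple[int, int]:
    return (
        sum(el.min_rep for el in elements),
        sum(el.max_rep for el in elements),
    )


def scan_pattern(
    sequence: str, pattern: str, motif_class: str = METAL_A
) -> list[MotifHit]:
    """All non-overlapping matches of ``pattern`` in ``sequence``.

    Scans left to right; at each anchor the longest match is taken and the
    scan resumes past it.  Positions are 1-based inclusive.
    """
    elements = parse_pattern(pattern)
    rx = _elements_to_regex(elements)
    min_len, max_len = _span_bounds(elements)
    hits: list[MotifHit] = []
    n = len(sequence)
    i = 0
    while i <= n - min_len:
        matched = 0
        for length in range(min(max_len, n - i), min_len - 1, -1):
            if rx.fullmatch(sequence, i, i + length):
                matched = length
                break
        if matched:
            hits.append(
                MotifHit(
                    motif_class=motif_class,
                    start=i + 1,
                    end=i + matched,
                    matched_text=sequence[i : i + matched],
                )
            )
            i += matched
        else:
            i += 1
    return hits


def _ctd_window_start(seq_len: int, ctd_fraction: float) -> int:
    """0-based start index of the C-terminal search window."""
    return seq_len - int(seq_len * ctd_fraction)


def detect_heptads(sequence: str, cfg: MotifConfig) -> Optional[MotifHit]:
    """Longest tandem run of CTD heptads, or None.

    Each 7-mer of the run must match the heptad consensus with at most
    ``heptad_max_mismatch`` mismatches; the run must start inside the
    C-terminal window and comprise at least ``heptad_min_repeats`` copies.
    Score = run length (number of repeats).
    """
    if len(sequence) < 7:
        return None
    consensus = parse_pattern(cfg.heptad_consensus)
    if len(consensus) != 7 or any((e.min_rep, e.max_rep) != (1, 1) for e in consensus):
        raise ValueError("heptad consensus must describe exactly 7 positions")
    allowed = [e.allowed for e in consensus]

    def mismatches(p: int) -> int:
        return sum(
            1
            for j in range(7)
            if allowed[j] is not None and sequence[p + j] not in allowed[j]
        )

    w0 = _ctd_window_start(len(sequence), cfg.ctd_fraction)
    best_run, best_start = 0, -1
    for p in range(w0, len(sequence) - 6):
        run = 0
        q = p
        while q + 7 <= len(sequence) and mismatches(q) <= cfg.heptad_max_mismatch:
            run += 1
            q += 7
        if run > best_run:
            best_run, best_start = run, p
    if best_run < max(cfg.heptad_min_repeats, 1):
        return None
    start = best_start + 1
    end = best_start + 7 * best_run
    return MotifHit(
        motif_class=HEPTAD,
        start=start,
        end=end,
        matched_text=sequence[best_start : best_start + 7 * best_run],
        score=best_run,
    )


def count_gwwg(sequence: str, cfg: MotifConfig) -> int:
    """Greedy left-to-right count of non-overlapping GW or WG dimers in the
    C-terminal window ("GWG" contributes exactly one)."""
    w0 = _ctd_window_start(len(sequence), cfg.ctd_fraction)
    window = sequence[w0:]
    count = 0
    i = 0
    while i < len(window) - 1:
        if window[i : i + 2] in ("GW", "WG"):
            count += 1
            i += 2
        else:
            i += 1
    return count


def detect_cyc_ypxf(sequence: str, cfg: MotifConfig) -> Optional[MotifHit]:
    """Detect the bipartite CYC-YPxF motif.

    A FULL hit requires a CYC sub-motif match followed by a YPxF match with
    at most ``cyc_ypxf_max_spacer`` residues in between; the hit spans the
    first to last matched residue and the leftmost full hit wins.  A PARTIAL
    hit (shortened CYC-YP, typical of bryophyte NRPE1-like subunits) is a
    CYC match with no qualifying YPxF downstream.  Returns None when the CYC
    sub-motif is absent.
    """
    cyc_hits = scan_pattern(sequence, cfg.cyc_pattern, motif_class=CYC_YP_PARTIAL)
    if not cyc_hits:
        return None
    yp_elements = parse_pattern(cfg.ypxf_pattern)
    yp_rx = _elements_to_regex(yp_elements)
    yp_min, yp_max = _span_bounds(yp_elements)
    for cyc in cyc_hits:
        # Search for a YPxF start within the spacer bound after the CYC end.
        for start0 in range(cyc.end, cyc.end + cfg.cyc_ypxf_max_spacer + 1):
            if start0 + yp_min > len(sequence):
                break
            for length in range(min(yp_max, len(sequence) - start0), yp_min - 1, -1):
                if yp_rx.fullmatch(sequence, start0, start0 + length):
                    return MotifHit(
                        motif_class=CYC_YPXF,
                        start=cyc.start,
                        end=start0 + length,
                        matched_text=sequence[cyc.start - 1 : start0 + length],
                        score=1.0,
                    )
    first = cyc_hits[0]
    return MotifHit(
        motif_class=CYC_YP_PARTIAL,
        start=first.start,
        end=first.end,
        matched_text=first.matched_text,
        score=1.0,
    )


def scan_record(record: ProteinRecord, cfg: MotifConfig) -> dict:
    """Run every scanner on one record and collect the evidence."""
    heptad = detect_heptads(record.sequence, cfg)
    cyc = detect_cyc_ypxf(record.sequence, cfg)
    return {
        "heptad": heptad,
        "gwwg_count": count_gwwg(record.sequence, cfg),
        "cyc": cyc,
    }


def classify_evidence(
    heptad_repeats: int,
    gwwg_count: int,
    cyc_full: bool,
    cyc_partial: bool,
    bryophyte: bool,
    cfg: MotifConfig,
) -> tuple[str, str]:
    """Apply the classification rule table to an evidence vector.

    Rules are tried in order, so exactly one fires:

    * R1: heptad repeats present -> B1_like (Pol II);
    * R2: full CYC-YPxF, no heptads -> D1_like (Pol IV);
    * R3: repeated GW/WG, no heptads, no full or partial CYC -> E1_like (Pol V);
    * R4: partial CYC-YP with repeated GW/WG, or partial CYC-YP in a
      bryophyte-flagged record -> DE_like (fourth cluster);
    * R5: otherwise unclassified.
    """
    has_heptad = heptad_repeats >= max(cfg.heptad_min_repeats, 1)
    gw_repeated = gwwg_count >= cfg.gwwg_min_count
    if has_heptad:
        return B1_LIKE, "R1"
    if cyc_full:
        return D1_LIKE, "R2"
    if gw_repeated and not cyc_partial:
        return E1_LIKE, "R3"
    if cyc_partial and (gw_repeated or bryophyte):
        return DE_LIKE, "R4"
    return UNCLASSIFIED, "R5"


def classify_subunit(
    record: ProteinRecord,
    hits: Optional[Mapping] = None,
    cfg: MotifConfig = MotifConfig(),
) -> ClassificationCall:
    """Classify one subunit by its motif content."""
    if hits is None:
        hits = scan_record(record, cfg)
    heptad = hits.get("heptad")
    cyc = hits.get("cyc")
    heptad_repeats = int(heptad.score) if heptad is not None else 0
    gwwg_count = int(hits.get("gwwg_count", 0))
    cyc_full = cyc is not None and cyc.motif_class == CYC_YPXF
    cyc_partial = cyc is not None and cyc.motif_class == CYC_YP_PARTIAL
    label, rule = classify_evidence(
        heptad_repeats=heptad_repeats,
        gwwg_count=gwwg_count,
        cyc_full=cyc_full,
        cyc_partial=cyc_partial,
        bryophyte=record.is_bryophyte,
        cfg=cfg,
    )
    return ClassificationCall(
        record_id=record.id,
        label=label,
        evidence={
            "heptad_repeats": heptad_repeats,
            "gwwg_count": gwwg_count,
            "cyc_full": int(cyc_full),
            "cyc_partial": int(cyc_partial),
        },
        rule_fired=rule,
    )
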