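"""Basidiospore morphometry summaries.

Taxonomic descriptions report spore dimensions as

    (a) b-c (d) x (e) f-g (h) um, [avX = m1 +/- s1 x m2 +/- s2 um, Qm = q, n = i x j]

where a/d (and e/h) are the extreme lengths (widths) recorded, b-c (f-g)
the 5th-95th percentile range, avX the mean length x width with standard
deviation, Qm the mean of the per-spore Q coefficient (length/width ratio),
i the measurements per collection and j the number of collections.

Percentiles use linear interpolation between closest ranks (numpy's
default, the "type 7" convention); the standard deviation uses the n-1
denominator.  Qm is the mean of ratios, never the ratio of means — a
warning is logged when the two disagree by more than 5%.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError

logger = logging.getLogger(__name__)

EN_DASH = "–"


@dataclass(frozen=True)
class SporeMeasurementSet:
    """Raw (length, width, collection) measurement triples, in micrometres."""

    records: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise InputError("need at least 2 spore measurements")
        for L, w, _ in self.records:
            if L <= 0 or w <= 0:
                raise InputError(f"non-positive spore dimension: {L} x {w}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([r[0] for r in self.records], dtype=float)

    @property
    def widths(self) -> np.ndarray:
        return np.array([r[1] for r in self.records], dtype=float)

    @property
    def collections(self) -> list[str]:
        return sorted({r[2] for r in self.records})

    @property
    def j(self) -> int:
        """Number of collections measured."""
        return len(self.collections)

    @property
    def i(self) -> int:
        """Measurements per collection (rounded mean when unequal)."""
        counts = [sum(1 for r in self.records if r[2] == c) for c in self.collections]
        return counts[0] if len(set(counts)) == 1 else round(len(self.records) / self.j)

    @property
    def n(self) -> int:
        return len(self.records)

    @classmethod
    def from_tsv(cls, text: str) -> "SporeMeasurementSet":
        """Parse a TSV of length <TAB> width <TAB> collection (header optional)."""
        records = []
        for ln, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if parts[0].lower() in ("length", "len"):
                continue
            if len(parts) < 2:
                raise InputError(f"measurement line {ln} needs length and width: {line!r}")
            coll = parts[2] if len(parts) > 2 else "collection1"
            try:
                records.append((float(parts[0]), float(parts[1]), coll))
            except ValueError:
                raise InputError(f"non-numeric measurement on line {ln}: {line!r}") from None
        return cls(tuple(records))


@dataclass(frozen=True)
class SporeSummary:
    """The statistics behind one printed spore-dimension line."""

    a: float  # minimum length
    b: float  # 5th percentile length
    c: float  # 95th percentile length
    d: float  # maximum length
    e: float  # minimum width
    f: float  # 5th percentile width
    g: float  # 95th percentile width
    h: float  # maximum width
    avx_len: float
    avx_wid: float
    sd_len: float
    sd_wid: float
    qm: float
    i: int
    j: int
    n: int

    @property
    def n_text(self) -> str:
        return f"{self.i} × {self.j}"


def summarize_spores(measurements: SporeMeasurementSet) -> SporeSummary:
    """Compute the spore-dimension summary from raw measurements."""
    L = measurements.lengths
    w = measurements.widths
    q = L / w
    qm = float(np.mean(q))
    ratio_of_means = float(np.mean(L) / np.mean(w))
    if abs(qm - ratio_of_means) > 0.05 * qm:
        logger.warning(
            "mean of ratios (Qm=%.3f) and ratio of means (%.3f) disagree by >5%%",
            qm,
            ratio_of_means,
        )
    return SporeSummary(
        a=float(L.min()),
        b=float(np.percentile(L, 5)),
        c=float(np.percentile(L, 95)),
        d=float(L.max()),
        e=float(w.min()),
        f=float(np.percentile(w, 5)),
        g=float(np.percentile(w, 95)),
        h=float(w.max()),
        avx_len=float(L.mean()),
        avx_wid=float(w.mean()),
        sd_len=float(L.std(ddof=1)),
        sd_wid=float(w.std(ddof=1)),
        qm=qm,
        i=measurements.i,
        j=measurements.j,
        n=measurements.n,
    )


#: rounding profiles: (range decimals, mean decimals, sd decimals, Qm decimals)
ROUNDING_PROFILES = {"default": (1, 1, 2, 2)}


def _fmt_range(x: float, decimals: int) -> str:
    """Round and trim a trailing '.0' the way printed ranges do (6.0 -> 6)."""
    r = round(x, decimals)
    return str(int(r)) if float(r).is_integer() else f"{r:.{decimals}f}"


def render_summary(
    summary: SporeSummary, rounding_profile: str = "default", dash: str = EN_DASH
) -> str:
    """Render the exact description grammar, e.g.
    ``(5.5–) 6–6.5 (–7) × (4.2–) 4.5–4.8 (–5.1) μm, [avX = 6.2 ± 0.67 × 4.6 ± 0.45 μm, Qm = 1.32, n = 20 × 10]``.
    """
    try:
        rdec, mdec, sdec, qdec = ROUNDING_PROFILES[rounding_profile]
    except KeyError:
        raise InputError(f"unknown rounding profile {rounding_profile!r}") from None
    s = summary
    rng = lambda x: _fmt_range(x, rdec)  # noqa: E731
    return (
        f"({rng(s.a)}{dash}) {rng(s.b)}{dash}{rng(s.c)} ({dash}{rng(s.d)}) × "
        f"({rng(s.e)}{dash}) {rng(s.f)}{dash}{rng(s.g)} ({dash}{rng(s.h)}) μm, "
        f"[avX = {s.avx_len:.{mdec}f} ± {s.sd_len:.{sdec}f} × "
        f"{s.avx_wid:.{mdec}f} ± {s.sd_wid:.{sdec}f} μm, "
        f"Qm = {s.qm:.{qdec}f}, n = {s.i} × {s.j}]"
    )


_NUM = r"(\d+(?:\.\d+)?)"
_SUMMARY_RE = re.compile(
    rf"\({_NUM}[–-]\)\s+{_NUM}[–-]{_NUM}\s+\([–-]{_NUM}\)\s+×\s+"
    rf"\({_NUM}[–-]\)\s+{_NUM}[–-]{_NUM}\s+\([–-]{_NUM}\)\s+μm,\s+"
    rf"\[avX\s+=\s+{_NUM}\s+±\s+{_NUM}\s+×\s+{_NUM}\s+±\s+{_NUM}\s+μm,\s+"
    rf"Qm\s+=\s+{_NUM},\s+n\s+=\s+(\d+)\s+×\s+(\d+)\]"
)


def parse_summary(text: str) -> SporeSummary:
    """Parse a rendered summary back into its numeric fields (round-trip aid)."""
    m = _SUMMARY_RE.fullmatch(text.strip())
    if not m:
        raise InputError(f"string does not match the spore-summary grammar: {text!r}")
    v = [float(x) for x in m.groups()[:13]]
    i, j = int(m.group(14)), int(m.group(15))
    return SporeSummary(
        a=v[0], b=v[1], c=v[2], d=v[3], e=v[4], f=v[5], g=v[6], h=v[7],
        avx_len=v[8], sd_len=v[9], avx_wid=v[10], sd_wid=v[11], qm=v[12],
        i=i, j=j, n=i * j,
    )


def matches_grammar(text: str) -> bool:
    return _SUMMARY_RE.fullmatch(text.strip()) is not None


def min_max_range(values: Iterable[float], decimals: int = 1, dash: str = EN_DASH) -> str:
    """Simple min-max range helper for basidia/cheilocystidia dimensions."""
    vals = list(values)
    if not vals:
        raise InputError("no values")
    return f"{_fmt_range(min(vals), decimals)}{dash}{_fmt_range(max(vals), decimals)}"
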