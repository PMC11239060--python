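"""Bundled example data.

Two curated polymorphic-position matrices observed among ITS sequences of
closely related *Agaricus* sect. *Minores* specimens, plus a small marker
demonstration community.  Each curated matrix lists only the variable
alignment positions; :func:`_embed` plants those states into a shared,
deterministic background sequence so that every pipeline stage can run on
a full-length alignment.  The background is identical across samples, so
the embedded matrices have exactly the listed positions variable.

Deletions printed at interior positions are encoded as internal gaps
(real character states); all rows share the conserved anchor motif at the
alignment start so local coordinates resolve.
"""

from __future__ import annotations

import numpy as np

from .alignment import ANCHOR_MOTIF, AlignedMatrix

_BACKGROUND_SEED = 11  # fixed: the background is part of the dataset, not a free parameter

#: Polymorphic positions among five A. glabriusculus and eleven
#: A. badiosquamulosus specimens (16 samples x 21 variable positions).
GLABRIUSCULUS_BADIOSQUAMULOSUS_POSITIONS = (
    9, 10, 11, 12, 13, 127, 222, 226, 279, 298, 306,
    314, 440, 522, 535, 571, 651, 669, 696, 701, 720,
)
GLABRIUSCULUS_BADIOSQUAMULOSUS_STATES = {
    "TS2":    "----TTCGACTTTACAA-CTC",
    "TS10":   "----TKCGACTWYRCAM-STC",
    "TS11":   "----TKCGACTWYRCAM-STC",
    "SH7":    "TTTATTCGACTTTACAA-GTT",
    "SH291L": "TTTATTCGACTTTACAA-GTT",
    "M4":     "----TTCGATCATGTGATCGC",
    "TS57":   "----TTCGRTCATGTGATCGC",
    "F11":    "----TTRGATCATGTGATCTC",
    "F5":     "----TTCRATCATGTGATCTC",
    "F4":     "----TTCRATCATGTGATCTC",
    "F3":     "----TTCRATCATGTGATCTC",
    "M22":    "----TTCRATCATGTGATCTC",
    "M6":     "----WTCGATCATGTGATCTC",
    "M28":    "----TTCGATCATGTGATCTC",
    "F53":    "----TTCGATCATGTGATCTC",
    "CM09":   "----TTCGATCATGTGATCTC",
}
GLABRIUSCULUS_SAMPLES = ("TS2", "TS10", "TS11", "SH7", "SH291L")

#: Polymorphic positions among nine A. dunensis specimens (9 x 8).
DUNENSIS_POSITIONS = (239, 296, 304, 544, 559, 652, 664, 665)
DUNENSIS_STATES = {
    "BWL01": "GGTTTG--",
    "BWN34": "GGTTTG--",
    "BWN64": "GGTTTG--",
    "L99":   "RGTTYGGT",
    "L2":    "RGTTYGGT",
    "LS4":   "GGTTTGGT",
    "TS56":  "AR-YCGGT",
    "BWN67": "AA-TCGGT",
    "BWN85": "AA-CCAGT",
}


def _background(length: int) -> str:
    """Deterministic shared background starting with a concrete anchor."""
    rng = np.random.default_rng(_BACKGROUND_SEED)
    anchor = ANCHOR_MOTIF.replace("Y", "T")  # TTGAATT
    tail = "".join(rng.choice(list("ACGT"), size=length - len(anchor)))
    return anchor + tail


def _embed(
    positions: tuple[int, ...],
    states: dict[str, str],
    length: int,
    groups: dict[str, str],
) -> AlignedMatrix:
    bg = _background(length)
    records = []
    for sample, row_states in states.items():
        row = list(bg)
        for pos, char in zip(positions, row_states):
            row[pos - 1] = char
        records.append((sample, "".join(row)))
    return AlignedMatrix(records, groups)


def load_glabriusculus_badiosquamulosus() -> AlignedMatrix:
    """16-sample alignment of the two sister species, 730 columns."""
    groups = {
        s: ("A_glabriusculus" if s in GLABRIUSCULUS_SAMPLES else "A_badiosquamulosus")
        for s in GLABRIUSCULUS_BADIOSQUAMULOSUS_STATES
    }
    return _embed(
        GLABRIUSCULUS_BADIOSQUAMULOSUS_POSITIONS,
        GLABRIUSCULUS_BADIOSQUAMULOSUS_STATES,
        730,
        groups,
    )


def load_dunensis() -> AlignedMatrix:
    """Nine-sample A. dunensis alignment, 700 columns."""
    groups = {s: "A_dunensis" for s in DUNENSIS_STATES}
    return _embed(DUNENSIS_POSITIONS, DUNENSIS_STATES, 700, groups)


def load_marker_demo() -> AlignedMatrix:
    """Four-sample, 500-column community built so that the target species
    carries exactly the diagnostic characters of the published-style marker
    notation: a single C at local position 200 inside ``aatcttcttcccg`` and a
    double TT at 420-421 inside ``attccttggagca``.

    Rows are gap-free with the anchor at column 1, so local positions equal
    alignment columns.
    """
    bg = list(_background(500))
    bg[193:206] = list("AATCTTCTTCCCG")  # columns 194..206
    bg[414:427] = list("ATTCCTTGGAGCA")  # columns 415..427
    target = "".join(bg)
    other = list(bg)
    other[199] = "T"  # column 200: C in the target, T outside
    other[419] = "C"  # columns 420-421: TT in the target, CC outside
    other[420] = "C"
    other = "".join(other)
    records = [
        ("badio_1", target),
        ("badio_2", target),
        ("out_1", other),
        ("out_2", other),
    ]
    groups = {
        "badio_1": "A_badiosquamulosus",
        "badio_2": "A_badiosquamulosus",
        "out_1": "outgroup",
        "out_2": "outgroup",
    }
    return AlignedMatrix(records, groups)
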