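"""Three-round climbing fractionation: trial outcomes -> ordinal fraction labels.

A cohort of flies is repeatedly split at a partition in a vertical tube.
Round 1 splits the cohort into a top and a bottom half; each half is split
again in round 2.  Flies with discordant round-1/round-2 outcomes (top then
bottom, or bottom then top) stop there and are labelled "middle" (they were
in the top in 1 of 2 trials).  Flies with concordant outcomes get a third
round, producing the remaining four labels:

    ===========  ==================  =====
    outcome      trials in top       label
    ===========  ==================  =====
    (T, T, T)    3 of 3              top
    (T, T, B)    2 of 3              mid-top
    (T, B) or
    (B, T)       1 of 2              middle
    (B, B, T)    1 of 3              mid-bottom
    (B, B, B)    0 of 3              bottom
    ===========  ==================  =====

Labels are stored as integers 0 (bottom) .. 4 (top); the canonical string
mapping tolerates the "mid-top"/"top-mid" naming inconsistency found in
informal descriptions of the assay.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

TOP = "T"
BOTTOM = "B"

#: Ordinal fraction labels, bottom to top.
FRACTION_NAMES = ("bottom", "mid-bottom", "middle", "mid-top", "top")

_ALIASES = {
    "bottom": 0,
    "mid-bottom": 1,
    "bottom-mid": 1,
    "middle": 2,
    "mid-top": 3,
    "top-mid": 3,
    "top": 4,
}


def fraction_to_int(label: int | str) -> int:
    """Canonical integer (0..4) for a fraction label given as int or string."""
    if isinstance(label, (int, np.integer)):
        if not 0 <= int(label) <= 4:
            raise ValueError(f"fraction level out of range: {label}")
        return int(label)
    key = str(label).strip().lower().replace("_", "-").replace(" ", "-")
    if key not in _ALIASES:
        raise ValueError(f"unknown fraction label: {label!r}")
    return _ALIASES[key]


def fraction_to_name(level: int) -> str:
    return FRACTION_NAMES[fraction_to_int(level)]


_OUTCOME_TABLE = {
    ("T", "T", "T"): 4,
    ("T", "T", "B"): 3,
    ("T", "B"): 2,
    ("B", "T"): 2,
    ("B", "B", "T"): 1,
    ("B", "B", "B"): 0,
}


def assign_fraction(rounds: Sequence[str]) -> int:
    """Map a per-fly sequence of round outcomes to its ordinal fraction.

    Parameters
    ----------
    rounds
        Sequence of 2 or 3 values from {"T", "B"}.  Length-2 sequences must
        be the discordant pairs (a discordant fly never gets a third round);
        length-3 sequences must start with a concordant pair.

    Returns
    -------
    int
        Ordinal level: 0=bottom, 1=mid-bottom, 2=middle, 3=mid-top, 4=top.
    """
    key = tuple(str(r).upper() for r in rounds)
    if any(r not in ("T", "B") for r in key):
        raise ValueError(f"round outcomes must be 'T' or 'B', got {rounds!r}")
    if key not in _OUTCOME_TABLE:
        raise ValueError(
            f"invalid trial sequence {rounds!r}: under the adopted branching, "
            "discordant round-1/2 flies stop after two rounds as 'middle' and "
            "only concordant flies receive a third round"
        )
    return _OUTCOME_TABLE[key]


def branching_probabilities(p: float) -> np.ndarray:
    """Exact label probabilities under the branching rule, for per-round
    top-probability ``p``.

    Enumerating the branching tree: concordant flies (TT or BB) get a third
    round, discordant flies stop as "middle", so

        bottom     = (1-p)^3
        mid-bottom = (1-p)^2 p
        middle     = 2 p (1-p)
        mid-top    = p^2 (1-p)
        top        = p^3

    Returns probabilities in ordinal order (bottom .. top); they sum to 1
    for any p in [0, 1].
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    q = 1.0 - p
    out = np.array([q**3, q**2 * p, 2 * p * q, p**2 * q, p**3], dtype=float)
    return out


def outcomes_to_fractions(outcomes: Iterable[Sequence[str]]) -> np.ndarray:
    """Vector version of :func:`assign_fraction`."""
    return np.array([assign_fraction(o) for o in outcomes], dtype=int)
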