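"""Fluorescent-protein catalog and barcode combinatorics.

A two-member barcode is an unordered *combination* of two distinct FPs:
emission spectra cannot distinguish which FP sits first in the construct,
so 18 FPs yield C(18,2) = 153 barcodes. At the sequence level order *is*
observable, and the reference set for read assignment enumerates ordered
pairs (permutations) instead: 18 x 17 = 306 two-FP constructs, or 324
ordered possibilities when the 18 single-FP references are counted with
them as in the pooled-library analysis.
"""

from __future__ import annotations

from itertools import combinations, permutations
from typing import Sequence

#: The 18-FP panel used throughout, in fixed catalog order. Tie-breaks in
#: classification and read assignment resolve by position in this list.
DEFAULT_FP_NAMES: tuple[str, ...] = (
    "EBFP2",
    "mTagBFP2",
    "mT-Sapphire",
    "mAmetrine",
    "mCerulean3",
    "LSSmOrange",
    "mBeRFP",
    "mTFP1",
    "EGFP",
    "CyOFP1",
    "mClover3",
    "mVenus",
    "mPapaya",
    "mOrange2",
    "mRuby3",
    "mKate2",
    "mCardinal",
    "miRFP670",
)

#: Label of the background basis column; never a callable class.
AUTOFLUORESCENCE_LABEL = "autofluorescence"

#: Default number of spectral detector channels.
DEFAULT_N_CHANNELS = 48


def unordered_pairs(labels: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered pairs of distinct labels (combinations without replacement).

    Pairs preserve catalog order within the tuple; 18 labels give 153 pairs.
    """
    _check_unique(labels)
    return list(combinations(labels, 2))


def ordered_pairs(labels: Sequence[str]) -> list[tuple[str, str]]:
    """All ordered pairs of distinct labels; 18 labels give 306 permutations."""
    _check_unique(labels)
    return list(permutations(labels, 2))


def pair_label(fp1: str, fp2: str, sep: str = "-") -> str:
    """Canonical string id for an ordered construct, position 1 first."""
    return f"{fp1}{sep}{fp2}"


def _check_unique(labels: Sequence[str]) -> None:
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be unique")
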