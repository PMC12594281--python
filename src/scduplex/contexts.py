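"""Mutation context classification.

Single-base substitutions are classified into the standard 96 trinucleotide
contexts (pyrimidine-strand normalized), and small insertions/deletions into
the standard 83 indel context classes (type, length, repeat-unit count,
microhomology length), matching the COSMIC v3.2 orderings used throughout the
signature analysis.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical 96 SBS context labels, e.g. ``A[C>A]A`` ... ``T[T>G]T``.
SBS96_CONTEXTS: list[str] = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
]
SBS96_INDEX = {c: i for i, c in enumerate(SBS96_CONTEXTS)}

#: The 32 pyrimidine-centred trinucleotides, in a fixed order.
TRINUC32 = [
    f"{five}{mid}{three}" for mid in "CT" for five in BASES for three in BASES
]
TRINUC32_INDEX = {t: i for i, t in enumerate(TRINUC32)}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def normalize_trinuc(trinuc: str) -> str:
    """Map a trinucleotide to its pyrimidine-centred representative."""
    if trinuc[1] in "CT":
        return trinuc
    return revcomp(trinuc)


def sbs_context(trinuc: str, alt: str) -> str:
    """96-class label for a substitution given its reference trinucleotide.

    The reference trinucleotide is centred on the mutated base; purine
    reference bases are reverse-complemented onto the pyrimidine strand
    (e.g. G>T in 5'-AGA-3' becomes T[C>A]T).
    """
    ref = trinuc[1]
    if ref in "AG":
        trinuc = revcomp(trinuc)
        alt = COMPLEMENT[alt]
        ref = trinuc[1]
    if alt == ref or alt not in BASES:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    return f"{trinuc[0]}[{ref}>{alt}]{trinuc[2]}"


def _build_id83() -> list[str]:
    labels = []
    for base in "CT":
        labels += [f"1:Del:{base}:{i}" for i in range(6)]
    for base in "CT":
        labels += [f"1:Ins:{base}:{i}" for i in range(6)]
    for ln in (2, 3, 4, 5):
        labels += [f"{ln}:Del:R:{i}" for i in range(6)]
    for ln in (2, 3, 4, 5):
        labels += [f"{ln}:Ins:R:{i}" for i in range(6)]
    labels += ["2:Del:M:1"]
    labels += ["3:Del:M:1", "3:Del:M:2"]
    labels += [f"4:Del:M:{i}" for i in (1, 2, 3)]
    labels += [f"5:Del:M:{i}" for i in (1, 2, 3, 4, 5)]
    return labels


#: Canonical 83 indel context labels (COSMIC ID83 ordering).
ID83_CONTEXTS: list[str] = _build_id83()
ID83_INDEX = {c: i for i, c in enumerate(ID83_CONTEXTS)}

assert len(ID83_CONTEXTS) == 83


def left_align_indel(seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align and parsimony-trim a VCF-style indel.

    ``pos`` is 0-based; ``ref``/``alt`` include the shared anchor base.
    Returns the equivalent leftmost (pos, ref, alt). Distance rules and
    repeat counting are representation-dependent, so every indel is
    normalized before classification or filtering.
    """
    ref, alt = ref.upper(), alt.upper()
    # trim identical trailing bases
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim identical leading bases beyond the anchor
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0] and ref[1] == alt[1]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if len(ref) > 1 and len(alt) > 1:
        raise ValueError(f"not a simple indel: {ref}>{alt}")
    # shift left while the base preceding the event equals the last base of
    # the varying sequence
    varying = ref[1:] if len(ref) > 1 else alt[1:]
    while pos > 0 and varying and seq[pos] == varying[-1]:
        varying = seq[pos] + varying[:-1]
        pos -= 1
        anchor = seq[pos]
        if len(ref) > 1:
            ref, alt = anchor + varying, anchor
        else:
            ref, alt = anchor, anchor + varying
    return pos, ref, alt


def _canonical_base(b: str) -> str:
    return "T" if b in "AT" else "C"


def _lcp(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def classify_indel(seq: str, pos: int, ref: str, alt: str) -> str:
    """Classify an indel into one of the 83 context classes.

    ``seq`` is the full chromosome sequence, ``pos`` 0-based with VCF-style
    anchored ``ref``/``alt``. The indel is left-aligned first. Deletions of
    length >= 2 with no additional tandem copy but flanking sequence identity
    are assigned to the microhomology classes.
    """
    pos, ref, alt = left_align_indel(seq, pos, ref, alt)
    if len(ref) > 1 and len(alt) == 1:
        event, s = "Del", ref[1:]
    elif len(alt) > 1 and len(ref) == 1:
        event, s = "Ins", alt[1:]
    else:
        raise ValueError(f"not an indel: {ref}>{alt}")
    ln = len(s)
    if pos + len(ref) > len(seq) or pos < 0:
        raise ValueError("indel spans a contig end")
    start = pos + 1  # first varying reference base (Del) / insertion point (Ins)
    if ln == 1:
        base = s
        # homopolymer run of `base` containing / adjacent to the event site
        if event == "Del":
            run, i = 0, start
            while i < len(seq) and seq[i] == base:
                run += 1
                i += 1
            i = start - 1
            while i >= 0 and seq[i] == base:
                run += 1
                i -= 1
            num = min(run, 6) - 1  # run includes the deleted base
        else:
            run, i = 0, start
            while i < len(seq) and seq[i] == base:
                run += 1
                i += 1
            i = start - 1
            while i >= 0 and seq[i] == base:
                run += 1
                i -= 1
            num = min(run, 5)
        return f"1:{event}:{_canonical_base(base)}:{num}"
    lncls = min(ln, 5)
    # count tandem copies of s adjacent to the event
    copies = 0
    i = start if event == "Ins" else start + ln
    while seq[i : i + ln] == s:
        copies += 1
        i += ln
    i = start - ln
    while i >= 0 and seq[i : i + ln] == s:
        copies += 1
        i -= ln
    if event == "Ins":
        return f"{lncls}:Ins:R:{min(copies, 5)}"
    units = copies + 1  # including the deleted copy
    if units == 1:
        right = seq[start + ln :]
        left = seq[:start]
        mh = max(_lcp(s, right), _lcp(s[::-1], left[::-1]))
        mh = min(mh, ln - 1)
        if mh >= 1:
            if ln == 2:
                return "2:Del:M:1"
            return f"{lncls}:Del:M:{min(mh, 5)}"
    return f"{lncls}:Del:R:{min(units, 6) - 1}"


def trinuc_codes(seq_arr: np.ndarray) -> np.ndarray:
    """Vectorized pyrimidine-normalized trinucleotide code for every interior
    position of an integer-encoded (A=0,C=1,G=2,T=3) sequence.

    Returns an int array of length ``len(seq) - 2`` with values in [0, 32)
    indexing :data:`TRINUC32`, aligned to the centre base at offset i+1.
    Positions containing non-ACGT bases get code -1.
    """
    five, mid, three = seq_arr[:-2], seq_arr[1:-1], seq_arr[2:]
    valid = (five >= 0) & (mid >= 0) & (three >= 0)
    pyr = (mid == 1) | (mid == 3)
    # pyrimidine strand: code = (mid==T)*16 + five*4 + three
    fwd = (mid == 3).astype(np.int64) * 16 + five * 4 + three
    # purine strand: complement and reverse
    c_five, c_mid, c_three = 3 - three, 3 - mid, 3 - five
    rev = (c_mid == 3).astype(np.int64) * 16 + c_five * 4 + c_three
    out = np.where(pyr, fwd, rev)
    out[~valid] = -1
    return out


def stable_key(text: str) -> int:
    """Process-independent 31-bit key for seeding per-cell RNG substreams
    (Python's ``hash`` is salted per process)."""
    import zlib

    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def encode_seq(seq: str) -> np.ndarray:
    """Encode an ACGT string as int8 (A=0,C=1,G=2,T=3, other=-1)."""
    table = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]
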