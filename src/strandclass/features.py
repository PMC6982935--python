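"""Sequence-only feature extractors.

Four encoders that need nothing beyond the amino-acid sequence (plus a
configuration table):

* ``oaac`` — overall amino-acid composition, 20 values; either plain
  frequencies n_i / L or their square roots (the square-root variant is the
  default, as it tends to behave better as a classifier input);
* ``dipeptide`` — gapped dipeptide composition: for each gap g the frequency
  of every ordered residue pair (a, b) occurring at distance g + 1, with the
  denominator fixed at N - 1 for every gap; gaps {0, 1, 2} give 1200 columns;
* ``physicochemical_profile`` — a properties-by-positions matrix from a
  per-residue property table (AAindex-style, 28 scales by default);
* ``lse_profile`` — local structural entropy: a 1 x L profile where each
  position gets the mean of the values of all 4-mer windows covering it.

Composition counts run over the 20 standard residues; positions normalised to
``X`` are excluded from both the counts and the denominator of ``oaac``, and
property tables impute ``X`` with the per-property table mean.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

from .types import (
    AMINO_ACIDS,
    FeatureBlock,
    PropertyTable,
    ProteinRecord,
    ResidueProfile,
    StrandclassError,
)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Kyte-Doolittle hydropathy, the one real scale in the default table.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

DEFAULT_N_PHYSICOCHEMICAL = 28


def oaac(record: ProteinRecord, mode: str = "sqrt_frequency") -> FeatureBlock:
    """Overall amino-acid composition of one protein.

    Parameters
    ----------
    record
        The protein.
    mode
        ``"frequency"`` returns p_i = n_i / L for each of the 20 residues in
        canonical order; ``"sqrt_frequency"`` (default) returns sqrt(p_i).

    ``X`` positions are excluded from both n_i and L.  Raises if no countable
    residues remain.
    """
    if mode not in {"frequency", "sqrt_frequency"}:
        raise StrandclassError(f"unknown OAAC mode {mode!r}")
    counts = np.zeros(20)
    for ch in record.sequence:
        idx = _AA_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise StrandclassError(
            f"protein {record.id!r}: no countable residues for composition"
        )
    p = counts / total
    values = np.sqrt(p) if mode == "sqrt_frequency" else p
    return FeatureBlock(
        source="OAAC",
        labels=[f"p_{aa}" for aa in AMINO_ACIDS],
        values=values,
    )


def dipeptide(record: ProteinRecord, gaps: Sequence[int] = (0, 1, 2)) -> FeatureBlock:
    """Gapped dipeptide composition.

    For each gap ``g`` and ordered pair (a, b) of the 20 standard residues,
    counts positions j with s_j = a and s_{j+g+1} = b and divides by N - 1,
    where N is the sequence length.  The same N - 1 denominator is used for
    every gap, so the gap-g block sums to (N - 1 - g) / (N - 1) for fully
    standard sequences.  Column order: gap-major, then first residue, then
    second residue.
    """
    gaps = list(gaps)
    if not gaps or any(g < 0 for g in gaps):
        raise StrandclassError("gaps must be a non-empty list of non-negative ints")
    seq = record.sequence
    n = len(seq)
    if n < max(gaps) + 2:
        raise StrandclassError(
            f"protein {record.id!r}: length {n} too short for gap {max(gaps)} "
            f"(needs at least {max(gaps) + 2})"
        )
    codes = np.array([_AA_INDEX.get(ch, -1) for ch in seq])
    labels: List[str] = []
    values = np.zeros(400 * len(gaps))
    for gi, g in enumerate(gaps):
        step = g + 1
        a = codes[: n - step]
        b = codes[step:]
        ok = (a >= 0) & (b >= 0)
        pair = a[ok] * 20 + b[ok]
        counts = np.bincount(pair, minlength=400).astype(float)
        values[gi * 400 : (gi + 1) * 400] = counts / (n - 1)
        labels.extend(
            f"g{g}_{x}{y}" for x in AMINO_ACIDS for y in AMINO_ACIDS
        )
    return FeatureBlock(source="dipeptide", labels=labels, values=values)


def physicochemical_profile(
    record: ProteinRecord, table: PropertyTable
) -> ResidueProfile:
    """Encode a sequence as a properties-by-positions matrix from a residue
    property table.  ``X`` positions take the per-property table mean."""
    table.require_standard_residues()
    mean = table.column_means()
    cols = [
        table.entries[ch] if ch in table.entries else mean for ch in record.sequence
    ]
    return ResidueProfile(
        protein_id=record.id,
        property_names=list(table.property_names),
        values=np.stack(cols, axis=1),
    )


def lse_profile(record: ProteinRecord, table4mer: PropertyTable) -> ResidueProfile:
    """Per-residue local structural entropy from a 4-mer lookup table.

    Each 4-mer window along the sequence has one table value; a residue's
    score is the mean over the 1-4 windows covering it.  4-mers absent from
    the table fall back to the table mean.
    """
    seq = record.sequence
    length = len(seq)
    if length < 4:
        raise StrandclassError(
            f"protein {record.id!r}: length {length} < 4, cannot window 4-mers"
        )
    fallback = float(table4mer.column_means()[0])
    window_vals = np.array(
        [
            float(table4mer.entries[seq[k : k + 4]][0])
            if seq[k : k + 4] in table4mer.entries
            else fallback
            for k in range(length - 3)
        ]
    )
    values = np.empty(length)
    for j in range(length):
        lo = max(0, j - 3)
        hi = min(j, length - 4)
        values[j] = window_vals[lo : hi + 1].mean()
    return ResidueProfile(
        protein_id=record.id,
        property_names=["lse"],
        values=values.reshape(1, -1),
    )


def default_property_table(n_properties: int = DEFAULT_N_PHYSICOCHEMICAL) -> PropertyTable:
    """Default physicochemical table: 28 scales over the 20 standard residues.

    Scale 1 is the Kyte-Doolittle hydropathy index; the remaining scales are
    synthetic stand-ins (deterministic pseudo-random values, standardised per
    scale) for the AAindex selection the method was designed around, whose
    exact accession list is not redistributed here.  Replace with your own
    AAindex subset via a TSV config for real analyses.
    """
    if n_properties < 1:
        raise StrandclassError("need at least one property")
    rng = np.random.default_rng(283_755)  # fixed: the table is configuration
    names = ["hydropathy_kd"] + [
        f"synthetic_scale_{i:02d}" for i in range(2, n_properties + 1)
    ]
    mat = np.empty((n_properties, 20))
    mat[0] = [KYTE_DOOLITTLE[aa] for aa in AMINO_ACIDS]
    if n_properties > 1:
        extra = rng.standard_normal((n_properties - 1, 20))
        extra = (extra - extra.mean(axis=1, keepdims=True)) / extra.std(
            axis=1, keepdims=True
        )
        mat[1:] = np.round(extra, 3)
    entries = {aa: mat[:, i] for i, aa in enumerate(AMINO_ACIDS)}
    return PropertyTable(property_names=names[:n_properties], entries=entries)


def default_lse_table() -> PropertyTable:
    """Synthetic stand-in for a local-structural-entropy 4-mer table.

    Values are sums of a fixed per-residue conformational-flexibility
    propensity (deterministic pseudo-random, scaled to roughly [0, 1]) over
    the 4 residues of each 4-mer, enumerated for all 160 000 standard 4-mers.
    Replace via a TSV config to use a published table.
    """
    rng = np.random.default_rng(164_929)
    propensity = rng.uniform(0.05, 0.2, size=20)
    aa = list(AMINO_ACIDS)
    vals = {}
    for i1 in range(20):
        for i2 in range(20):
            for i3 in range(20):
                base = propensity[i1] + propensity[i2] + propensity[i3]
                for i4 in range(20):
                    vals[aa[i1] + aa[i2] + aa[i3] + aa[i4]] = [
                        base + propensity[i4]
                    ]
    return PropertyTable(property_names=["lse"], entries=vals)
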