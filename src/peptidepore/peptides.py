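"""Peptide design and CD-spectrum utilities.

Covers the small computations used when designing hydrophilic variants
of a pore-forming β-hairpin peptide and processing their circular-
dichroism spectra: hydropathy profiles (Kyte–Doolittle and
Engelman/GES scales), point substitutions, molar residue ellipticity,
Savitzky–Golay smoothing and baseline subtraction.

The MRE conversion follows from the declared units — observed
ellipticity Y in mdeg, path length L in cm, peptide concentration C in
dmol·cm⁻³, n residues::

    MRE(λ) = (Y(λ) / 1000) / (L · C · n)    [deg·cm²·dmol⁻¹·res⁻¹]

(the factor 1000 converts mdeg to deg; with C in dmol·cm⁻³ no further
constant is dimensionally admissible).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "PeptideSequence",
    "CDSpectrum",
    "load_scale",
    "hydropathy_profile",
    "apply_substitutions",
    "mre_from_ellipticity",
    "smooth_spectrum",
    "subtract_baselines",
    "read_fasta",
    "write_fasta",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

_SCALE_FILES = {
    "kyte_doolittle": "kyte_doolittle.tsv",
    "engelman_ges": "engelman_ges.tsv",
}


@dataclass
class PeptideSequence:
    residues: str
    name: str = ""

    def __post_init__(self) -> None:
        bad = [(i + 1, r) for i, r in enumerate(self.residues)
               if r not in AMINO_ACIDS]
        if bad:
            pos, res = bad[0]
            raise ValueError(
                f"non-canonical residue {res!r} at position {pos} "
                f"in {self.name or 'sequence'}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class CDSpectrum:
    """A circular-dichroism spectrum with the metadata MRE needs.

    ``concentration`` is in dmol·cm⁻³ and ``path_length`` in cm (a
    0.2 mm microsampling disc is 0.02 cm).
    """

    wavelengths_nm: np.ndarray
    ellipticity_mdeg: np.ndarray
    path_length_cm: float
    concentration_dmol_cm3: float
    n_residues: int
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.ellipticity_mdeg = np.asarray(self.ellipticity_mdeg, dtype=float)
        if self.wavelengths_nm.size != self.ellipticity_mdeg.size:
            raise ValueError("wavelength and ellipticity lengths differ")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.path_length_cm <= 0 or self.concentration_dmol_cm3 <= 0:
            raise ValueError("path length and concentration must be positive")
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")


def load_scale(name: str = "kyte_doolittle") -> dict[str, float]:
    """Load a per-residue hydropathy scale shipped with the package."""
    try:
        fname = _SCALE_FILES[name]
    except KeyError:
        raise ValueError(f"unknown scale {name!r}; "
                         f"choose from {sorted(_SCALE_FILES)}") from None
    text = resources.files("peptidepore.data").joinpath(fname).read_text()
    scale: dict[str, float] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") \
                or line.startswith("residue"):
            continue
        res, value = line.split("\t")
        scale[res] = float(value)
    missing = AMINO_ACIDS - set(scale)
    if missing:
        raise ValueError(f"scale {name} missing residues {sorted(missing)}")
    return scale


def hydropathy_profile(seq: PeptideSequence,
                       scale: dict[str, float] | str = "kyte_doolittle",
                       window: int = 1) -> tuple[np.ndarray, float]:
    """Windowed hydropathy per position plus the whole-sequence mean.

    ``window`` must be odd; window 1 returns the raw per-residue scale
    values.  Near the ends the window shrinks to the available residues.
    """
    if isinstance(scale, str):
        scale = load_scale(scale)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    values = np.array([scale[r] for r in seq.residues])
    if window == 1:
        profile = values.copy()
    else:
        half = window // 2
        profile = np.array([
            values[max(0, i - half):i + half + 1].mean()
            for i in range(values.size)])
    return profile, float(values.mean())


def apply_substitutions(seq: PeptideSequence,
                        subs: list[tuple[int, str, str]]) -> PeptideSequence:
    """Apply 1-based (position, from, to) substitutions.

    The ``from`` residue must match the current sequence — a mismatch is
    an error, guarding against off-by-one design mistakes.  The new name
    is suffixed with the mutation list (e.g. ``_S11D``).
    """
    residues = list(seq.residues)
    tags = []
    for pos, frm, to in subs:
        if not 1 <= pos <= len(residues):
            raise ValueError(f"position {pos} outside 1..{len(residues)}")
        if residues[pos - 1] != frm:
            raise ValueError(
                f"expected {frm} at position {pos}, found {residues[pos - 1]}")
        if to not in AMINO_ACIDS:
            raise ValueError(f"non-canonical target residue {to!r}")
        residues[pos - 1] = to
        tags.append(f"{frm}{pos}{to}")
    name = seq.name + ("_" + "_".join(tags) if tags else "")
    return PeptideSequence("".join(residues), name=name)


def mre_from_ellipticity(spectrum: CDSpectrum) -> np.ndarray:
    """Molar residue ellipticity series (deg·cm²·dmol⁻¹·res⁻¹)."""
    return (spectrum.ellipticity_mdeg / 1000.0) / (
        spectrum.path_length_cm
        * spectrum.concentration_dmol_cm3
        * spectrum.n_residues)


def smooth_spectrum(values, width: int = 15, polyorder: int = 2) -> np.ndarray:
    """Savitzky–Golay smoothing (default convolution width 15, order 2).

    Output has the input's length; edge windows are handled by fitting
    the boundary polynomial (``mode='interp'``).  Polynomials up to
    ``polyorder`` pass through unchanged.
    """
    values = np.asarray(values, dtype=float)
    if width % 2 == 0:
        raise ValueError("width must be odd")
    if width > values.size:
        raise ValueError(f"width {width} exceeds series length {values.size}")
    if width <= polyorder:
        raise ValueError("width must exceed polyorder")
    return savgol_filter(values, window_length=width, polyorder=polyorder,
                         mode="interp")


def subtract_baselines(sample: CDSpectrum, buffer_blank: CDSpectrum,
                       expression_blank: CDSpectrum) -> CDSpectrum:
    """Subtract the buffer/disc blank and the expression-mixture blank."""
    for blank in (buffer_blank, expression_blank):
        if blank.wavelengths_nm.size != sample.wavelengths_nm.size \
                or not np.allclose(blank.wavelengths_nm,
                                   sample.wavelengths_nm):
            raise ValueError("blank wavelength grid does not match sample")
    corrected = (sample.ellipticity_mdeg
                 - buffer_blank.ellipticity_mdeg
                 - expression_blank.ellipticity_mdeg)
    return CDSpectrum(
        wavelengths_nm=sample.wavelengths_nm.copy(),
        ellipticity_mdeg=corrected,
        path_length_cm=sample.path_length_cm,
        concentration_dmol_cm3=sample.concentration_dmol_cm3,
        n_residues=sample.n_residues,
        label=sample.label + "_corrected")


def read_fasta(path: str | os.PathLike) -> list[PeptideSequence]:
    """Read peptide sequences from FASTA."""
    from Bio import SeqIO

    return [PeptideSequence(str(rec.seq).upper(), name=rec.id)
            for rec in SeqIO.parse(os.fspath(path), "fasta")]


def write_fasta(seqs: list[PeptideSequence], path: str | os.PathLike) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s.residues), id=s.name or f"peptide_{i}",
                         description="") for i, s in enumerate(seqs)]
    seqio_write(records, os.fspath(path), "fasta")


def bundled_sequences() -> list[PeptideSequence]:
    """The synthetic stand-in SVG28 family shipped with the package.

    These sequences are synthetic: they reproduce the design scheme of
    the SVG28 hydrophilic-variant family (a 28-residue β-hairpin with
    serines at positions 5/11/17/23 substituted to Asp or Asn), not the
    proprietary sequences themselves.  Replace the FASTA to analyse real
    designs.
    """
    text = resources.files("peptidepore.data") \
        .joinpath("svg28_synthetic.fasta").read_text()
    seqs = []
    name, chunks = None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                seqs.append(PeptideSequence("".join(chunks), name=name))
            name, chunks = line[1:].split()[0], []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        seqs.append(PeptideSequence("".join(chunks), name=name))
    return seqs
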