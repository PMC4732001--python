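"""Peak lists, precursor ion types and fragment-to-peak assignment.

Mass tolerances are additive: a relative (ppm) and an absolute (Da) term
are summed, so the window grows linearly with m/z.  Fragment ions are
singly charged; the adduct mass of the precursor ion type (including the
electron mass correction) converts neutral fragment masses to m/z, with
optional integer hydrogen shifts to cover homolytic/heterolytic cleavage
variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import ELECTRON_MASS, MONOISOTOPIC_MASS, PROTON_MASS
from .fragments import FragmentRef, fragment_mass, matchable_fragments

_H = MONOISOTOPIC_MASS["H"]
_NA = MONOISOTOPIC_MASS["Na"]
_K = MONOISOTOPIC_MASS["K"]
_N = MONOISOTOPIC_MASS["N"]
_O = MONOISOTOPIC_MASS["O"]
_C = MONOISOTOPIC_MASS["C"]
_CL = MONOISOTOPIC_MASS["Cl"]


@dataclass(frozen=True)
class PrecursorType:
    """A supported ion species: name, neutral->ion mass offset, polarity."""

    name: str
    adduct_mass: float  # Da added to the neutral mass, electron mass included
    polarity: int  # +1 or -1


# Offsets are (adduct formula mass) -/+ one electron mass for +/- ions.
PRECURSOR_TYPES: dict[str, PrecursorType] = {
    p.name: p
    for p in [
        PrecursorType("[M+H]+", PROTON_MASS, +1),
        PrecursorType("[M]+", -ELECTRON_MASS, +1),
        PrecursorType("[M]-", +ELECTRON_MASS, -1),
        PrecursorType("[M-H]-", -PROTON_MASS, -1),
        PrecursorType("[M+Na]+", _NA - ELECTRON_MASS, +1),
        PrecursorType("[M+K]+", _K - ELECTRON_MASS, +1),
        PrecursorType("[M+NH4]+", _N + 4 * _H - ELECTRON_MASS, +1),
        PrecursorType("[M+Cl]-", _CL + ELECTRON_MASS, -1),
        PrecursorType("[M+HCOO]-", _C + _H + 2 * _O + ELECTRON_MASS, -1),
        PrecursorType("[M+CH3COO]-", 2 * _C + 3 * _H + 2 * _O + ELECTRON_MASS, -1),
    ]
}


def get_precursor_type(name: str) -> PrecursorType:
    try:
        return PRECURSOR_TYPES[name]
    except KeyError:
        raise ValueError(
            f"unsupported precursor ion type {name!r}; "
            f"supported: {sorted(PRECURSOR_TYPES)}"
        ) from None


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity <= 0:
            raise ValueError("peak intensity must be positive")


@dataclass
class Spectrum:
    """An MS/MS peak list with its precursor context."""

    peaks: list[Peak]
    neutral_precursor_mass: float
    precursor_type: PrecursorType
    retention_time: float | None = None  # minutes

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def max_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)

    @property
    def precursor_ion_mz(self) -> float:
        return self.neutral_precursor_mass + self.precursor_type.adduct_mass


@dataclass(frozen=True)
class MatchSettings:
    relative_ppm: float = 5.0
    absolute_da: float = 0.001
    hydrogen_shifts: tuple[int, ...] = (-1, 0, 1)

    def __post_init__(self):
        if self.relative_ppm < 0 or self.absolute_da < 0:
            raise ValueError("mass tolerances must be non-negative")


@dataclass(frozen=True)
class MatchAssignment:
    peak: Peak
    fragment: FragmentRef
    hydrogen_shift: int
    matched_bde: float


def mass_tolerance(mz: float, settings: MatchSettings) -> float:
    """Additive mass window half-width at the given m/z, in Da."""
    return mz * settings.relative_ppm * 1e-6 + settings.absolute_da


def theoretical_ion_mz(
    neutral_fragment_mass: float, ptype: PrecursorType, h_shift: int = 0
) -> float:
    """m/z of the singly charged fragment ion with an integer H shift."""
    return neutral_fragment_mass + ptype.adduct_mass + h_shift * _H


def read_peak_list(path: str) -> list[Peak]:
    """Read a two-column text peak list (m/z intensity); '#' comments ignored."""
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'mz intensity'")
            peaks.append(Peak(float(parts[0]), float(parts[1])))
    return peaks


def match_peaks(
    spec: Spectrum,
    fragments: list[FragmentRef],
    settings: MatchSettings,
    structure=None,
    fragment_masses: dict[int, float] | None = None,
) -> list[MatchAssignment]:
    """Assign at most one fragment to each peak.

    Among all fragments whose ion m/z (over the allowed hydrogen shifts)
    falls within the additive tolerance of a peak, the fragment with the
    smallest cumulative cleaved-bond energy wins — the smallest possible
    score denominator.  Ties break on smaller absolute hydrogen shift,
    then smaller fragment mass, then the bitset encoding.

    ``fragment_masses`` may precompute neutral masses keyed by atom bitset;
    otherwise ``structure`` is required to compute them.
    """
    if fragment_masses is None:
        if structure is None:
            raise ValueError("need structure or precomputed fragment masses")
        fragments = matchable_fragments(fragments, structure)
        fragment_masses = {
            f.atom_bits: fragment_mass(f, structure) for f in fragments
        }

    ptype = spec.precursor_type
    assignments = []
    for peak in spec.peaks:
        tol = mass_tolerance(peak.mz, settings)
        candidates = []
        for f in fragments:
            fmass = fragment_masses[f.atom_bits]
            for h in settings.hydrogen_shifts:
                if abs(theoretical_ion_mz(fmass, ptype, h) - peak.mz) <= tol:
                    candidates.append((f.cleaved_bde, abs(h), fmass, f.atom_bits, h, f))
        if candidates:
            bde, _, _, _, h, frag = min(candidates, key=lambda c: c[:4] + (c[4],))
            assignments.append(MatchAssignment(peak, frag, h, bde))
    return assignments
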