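"""Nine-resonance triglyceride spectral model for vertebral bone marrow.

Marrow fat is essentially triglyceride.  Its 1H spectrum at 3 T shows nine
resolvable resonances whose relative areas are fixed by the average chemical
structure of the triglyceride molecule: the number of carbons per fatty-acid
chain (``chain_length``), the mean number of double bonds per chain
(``double_bonds``) and the mean number of methylene-interrupted
(diallylic) double-bond pairs (``methylene_interrupted``).  Given those
three numbers the proton count contributing to each resonance follows from
bookkeeping over the glycerol backbone and the three acyl chains, so the
whole fat spectrum has a single overall amplitude as the only free scale.

The nine resonances are grouped into the six lettered groups conventionally
used for marrow spectra (A through F); groups E and F overlap the water
resonance at 4.7 ppm and are therefore constrained to fixed ratios of the
well-resolved A+B area during fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

# 1H gyromagnetic ratio: Hz per ppm = field strength (T) * this value
GYROMAGNETIC_MHZ_PER_T = 42.577

WATER_PPM = 4.7

# Fat resonance chemical shifts (ppm) and their conventional group letters.
FAT_PPM: tuple[float, ...] = (0.90, 1.30, 1.59, 2.00, 2.25, 2.77, 4.20, 5.19, 5.31)

GROUP_OF_PPM: dict[float, str] = {
    0.90: "A",   # terminal methyl -(CH2)n-CH3
    1.30: "B",   # bulk methylene -(CH2)n-
    1.59: "B",   # beta-carboxyl -CO-CH2-CH2-
    2.00: "C",   # allylic -CH2-CH=CH-CH2-
    2.25: "C",   # alpha-carboxyl -CO-CH2-CH2-
    2.77: "D",   # diallylic -CH=CH-CH2-CH=CH-
    4.20: "E",   # glycerol -CH2-O-CO-
    5.19: "F",   # glycerol -CH-O-CO-
    5.31: "F",   # olefinic -CH=CH-
}

GROUPS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F")


@dataclass(frozen=True)
class TriglycerideComposition:
    """Average triglyceride chemical structure of the marrow fat.

    Defaults describe a moderately unsaturated depot fat typical of human
    bone marrow (mean chain length ~17.4 carbons, ~2.8 double bonds per
    triglyceride, ~0.7 of them methylene-interrupted).
    """

    chain_length: float = 17.4
    double_bonds: float = 2.8
    methylene_interrupted: float = 0.7

    def __post_init__(self) -> None:
        cl, ndb, nmidb = self.chain_length, self.double_bonds, self.methylene_interrupted
        if nmidb > ndb:
            raise ValueError("methylene_interrupted cannot exceed double_bonds")
        counts = self.proton_counts()
        bad = {p: c for p, c in counts.items() if c < 0}
        if bad:
            raise ValueError(f"composition implies negative proton counts at {bad}")

    def proton_counts(self) -> dict[float, float]:
        """Protons per triglyceride molecule contributing to each resonance."""
        cl, ndb, nmidb = self.chain_length, self.double_bonds, self.methylene_interrupted
        return {
            0.90: 9.0,
            1.30: 6.0 * (cl - 4.0) - 8.0 * ndb + 2.0 * nmidb,
            1.59: 6.0,
            2.00: 4.0 * (ndb - nmidb),
            2.25: 6.0,
            2.77: 2.0 * nmidb,
            4.20: 4.0,
            5.19: 1.0,
            5.31: 2.0 * ndb,
        }

    def group_areas(self) -> dict[str, float]:
        """Relative area (proton count) of each lettered peak group."""
        out = {g: 0.0 for g in GROUPS}
        for ppm, n in self.proton_counts().items():
            out[GROUP_OF_PPM[ppm]] += n
        return out

    def within_group_weights(self) -> dict[float, float]:
        """Fraction of its group's area carried by each individual resonance."""
        counts = self.proton_counts()
        groups = self.group_areas()
        return {
            ppm: (counts[ppm] / groups[GROUP_OF_PPM[ppm]] if groups[GROUP_OF_PPM[ppm]] > 0 else 0.0)
            for ppm in FAT_PPM
        }

    def constraint_ratios(self) -> tuple[float, float]:
        """(area E, area F) divided by area(A+B) — the fit constraints."""
        g = self.group_areas()
        ab = g["A"] + g["B"]
        if ab <= 0:
            raise ValueError("A+B area must be positive to define constraint ratios")
        return g["E"] / ab, g["F"] / ab


def ppm_to_hz(ppm: float, field_strength: float) -> float:
    """Chemical shift offset in Hz at the given static field (T)."""
    return ppm * field_strength * GYROMAGNETIC_MHZ_PER_T
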