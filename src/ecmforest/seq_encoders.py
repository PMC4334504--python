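"""Sequence-only feature encoders (159 features).

Blocks computed directly from the amino-acid string:

* functional-group frequencies (10) — side-chain chemistry groups that
  partition the 20 amino acids;
* Shannon entropies of the amino-acid and dipeptide compositions (2);
* per-amino-acid positional distribution, the population variance of
  occurrence offsets from the first occurrence (20);
* group-pair transition frequencies over adjacent residues (45);
* type-I pseudo amino-acid composition with 20 correlation tiers built
  from four physicochemical property scales (40);
* db4 discrete-wavelet statistics of three per-residue property signals (42).

Every encoder is a pure function: identical input and configuration give
bit-identical output.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pywt

from .io_formats import AMINO_ACIDS, ParseError

# ---------------------------------------------------------------------------
# functional groups
# ---------------------------------------------------------------------------

#: side-chain functional groups, in canonical order; the member sets
#: partition the 20-letter alphabet
FUNCTIONAL_GROUPS: tuple = (
    ("phenyl", frozenset("FWY")),
    ("carboxyl", frozenset("DE")),
    ("imidazole", frozenset("H")),
    ("primary_amine", frozenset("K")),
    ("guanidino", frozenset("R")),
    ("thiol", frozenset("C")),
    ("sulfur", frozenset("M")),
    ("amido", frozenset("QN")),
    ("hydroxyl", frozenset("ST")),
    ("nonpolar", frozenset("AGILVP")),
)

GROUP_NAMES = tuple(name for name, _ in FUNCTIONAL_GROUPS)

#: residue -> group index lookup
GROUP_OF = {aa: g for g, (_, members) in enumerate(FUNCTIONAL_GROUPS) for aa in members}

#: the 45 unordered group pairs, lexicographic over (i, j), i < j
GROUP_PAIRS = tuple((i, j) for i in range(10) for j in range(i + 1, 10))


# ---------------------------------------------------------------------------
# physicochemical property scales
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PropertyScale:
    """A named per-amino-acid numeric scale.

    Scales are standardized (zero mean, unit population SD across the 20
    amino acids) before entering the pseudo-composition correlation factors
    or the wavelet signals, so scales with different units are commensurate.
    """

    name: str
    values: Mapping[str, float]
    standardized: bool = False

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r}: missing amino acids {sorted(missing)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[a] for a in AMINO_ACIDS], dtype=float)

    def standardize(self) -> "PropertyScale":
        if self.standardized:
            return self
        arr = self.as_array()
        sd = arr.std()  # population SD
        if sd == 0:
            raise ValueError(f"scale {self.name!r} is constant; cannot standardize")
        z = (arr - arr.mean()) / sd
        return PropertyScale(self.name, dict(zip(AMINO_ACIDS, z)), True)


def read_property_scale(path, name: str | None = None) -> PropertyScale:
    """Read a scale from a two-column TSV (amino acid, value)."""
    from pathlib import Path

    path = Path(path)
    values: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split("\t")
        if len(tokens) != 2 or tokens[0] not in AMINO_ACIDS:
            raise ParseError(f"{path}:{lineno}: expected '<amino acid>\\t<value>'")
        values[tokens[0]] = float(tokens[1])
    return PropertyScale(name or path.stem, values)


# Kyte-Doolittle hydropathy index
HYDROPHOBICITY = PropertyScale(
    "hydrophobicity",
    {
        "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
        "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
        "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
        "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
    },
)

# Bhaskaran-Ponnuswamy average flexibility index
FLEXIBILITY = PropertyScale(
    "flexibility",
    {
        "A": 0.357, "C": 0.346, "D": 0.511, "E": 0.497, "F": 0.314,
        "G": 0.544, "H": 0.323, "I": 0.462, "K": 0.466, "L": 0.365,
        "M": 0.295, "N": 0.463, "P": 0.509, "Q": 0.493, "R": 0.529,
        "S": 0.507, "T": 0.444, "V": 0.386, "W": 0.305, "Y": 0.420,
    },
)

# side-chain net charge at physiological pH (His partially protonated)
NET_CHARGE = PropertyScale(
    "net_charge",
    {
        "A": 0.0, "C": 0.0, "D": -1.0, "E": -1.0, "F": 0.0,
        "G": 0.0, "H": 0.5, "I": 0.0, "K": 1.0, "L": 0.0,
        "M": 0.0, "N": 0.0, "P": 0.0, "Q": 0.0, "R": 1.0,
        "S": 0.0, "T": 0.0, "V": 0.0, "W": 0.0, "Y": 0.0,
    },
)

# mean accessible surface area in extended tripeptides (A^2), Rose et al.
ACCESSIBLE_SURFACE_AREA = PropertyScale(
    "accessible_surface_area",
    {
        "A": 118.1, "C": 146.1, "D": 158.7, "E": 186.2, "F": 222.8,
        "G": 88.1, "H": 202.5, "I": 181.0, "K": 225.8, "L": 193.1,
        "M": 203.4, "N": 165.5, "P": 146.8, "Q": 193.2, "R": 256.0,
        "S": 129.8, "T": 152.5, "V": 164.5, "W": 266.3, "Y": 236.8,
    },
)

#: the four scales entering the pseudo-composition correlation factors
PSEAAC_SCALES = (HYDROPHOBICITY, FLEXIBILITY, NET_CHARGE, ACCESSIBLE_SURFACE_AREA)

#: the three scales converted to wavelet signals
DWT_SCALES = (HYDROPHOBICITY, FLEXIBILITY, ACCESSIBLE_SURFACE_AREA)


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PseAACParams:
    """Type-I pseudo amino-acid composition parameters.

    ``eta`` correlation tiers add ``eta`` components to the 20 composition
    components; ``weight`` balances composition against sequence-order
    correlation.
    """

    eta: int = 20
    weight: float = 0.05

    def __post_init__(self) -> None:
        if self.eta < 1:
            raise ValueError("eta must be >= 1")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclasses.dataclass(frozen=True)
class DWTParams:
    """Multilevel wavelet decomposition parameters.

    A level-4 decomposition yields five sub-bands (cA4, cD4, cD3, cD2, cD1);
    the three coarsest are summarized by default, giving 2 + 4 x 3 = 14
    features per property signal and 42 in total over three properties.
    """

    wavelet: str = "db4"
    level: int = 4
    subbands: tuple = ("cA4", "cD4", "cD3")
    padding: str = "symmetric"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("level must be >= 1")
        valid = self.subband_names(self.level)
        unknown = [b for b in self.subbands if b not in valid]
        if unknown:
            raise ValueError(f"unknown sub-band(s) {unknown}; valid: {valid}")

    @staticmethod
    def subband_names(level: int) -> tuple:
        return ("cA%d" % level,) + tuple("cD%d" % d for d in range(level, 0, -1))

    @property
    def features_per_property(self) -> int:
        return 2 + 4 * len(self.subbands)

    def min_length(self) -> int:
        """Shortest signal admitting a full ``level``-deep decomposition."""
        filt = pywt.Wavelet(self.wavelet).dec_len
        return (filt - 1) * 2 ** self.level


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------


def ffg_frequencies(seq: str) -> np.ndarray:
    """Frequencies of the 10 side-chain functional groups; sums to 1."""
    if not seq:
        raise ValueError("empty sequence")
    counts = np.zeros(10)
    for residue in seq:
        counts[GROUP_OF[residue]] += 1
    return counts / len(seq)


def ffg_feature_names() -> list:
    return [f"ffg.{name}" for name in GROUP_NAMES]


def shannon_entropies(seq: str) -> np.ndarray:
    """Shannon entropy (bits) of amino-acid and dipeptide composition.

    Dipeptides are the L-1 overlapping pairs; 0 * log 0 is taken as 0.
    """
    if len(seq) < 2:
        raise ValueError("dipeptide entropy needs a sequence of length >= 2")
    return np.array([_entropy(Counter(seq)), _entropy(Counter(_dipeptides(seq)))])


def _dipeptides(seq: str):
    return (seq[i : i + 2] for i in range(len(seq) - 1))


def _entropy(counts: Counter) -> float:
    total = sum(counts.values())
    p = np.array([c / total for c in counts.values() if c > 0])
    return float(-(p * np.log2(p)).sum())


def entropy_feature_names() -> list:
    return ["entropy.aac", "entropy.dipeptide"]


def distribution_descriptor(seq: str) -> np.ndarray:
    """Positional spread of each amino acid.

    For amino acid *i* occurring at 0-based positions p_1 < ... < p_N, the
    offsets d_j = p_j - p_1 are taken and their population variance
    (denominator N) reported.  Absent or singleton amino acids give 0.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.zeros(20)
    for k, aa in enumerate(AMINO_ACIDS):
        pos = np.flatnonzero(arr == ord(aa))
        if pos.size >= 2:
            out[k] = np.var(pos - pos[0])
    return out


def distribution_feature_names() -> list:
    return [f"dist.{aa}" for aa in AMINO_ACIDS]


def transition_descriptor(seq: str) -> np.ndarray:
    """Adjacent-residue transition frequencies between functional groups.

    For each unordered group pair {g, h}, the number of adjacent residue
    pairs crossing between the groups (in either order) divided by the
    sequence length L.
    """
    if not seq:
        raise ValueError("empty sequence")
    L = len(seq)
    counts = np.zeros((10, 10))
    for a, b in zip(seq, seq[1:]):
        counts[GROUP_OF[a], GROUP_OF[b]] += 1
    return np.array([(counts[i, j] + counts[j, i]) / L for i, j in GROUP_PAIRS])


def transition_feature_names() -> list:
    return [f"trans.{GROUP_NAMES[i]}__{GROUP_NAMES[j]}" for i, j in GROUP_PAIRS]


def pseaac(
    seq: str,
    params: PseAACParams = PseAACParams(),
    scales: Sequence[PropertyScale] = PSEAAC_SCALES,
) -> np.ndarray:
    """Type-I pseudo amino-acid composition (20 + eta components, sums to 1).

    The tier-k correlation factor averages, over all residue pairs k apart,
    the squared property differences averaged over the standardized scales:

        theta_k = (1 / (L - k)) * sum_j Theta(R_j, R_{j+k})
        Theta(a, b) = mean_p (P_p(a) - P_p(b))^2

    Components 1..20 are f_u / (1 + w * sum theta); components 20+k are
    w * theta_k / (1 + w * sum theta).
    """
    L = len(seq)
    if L <= params.eta:
        raise ValueError(
            f"sequence length {L} must exceed the tier count eta={params.eta}"
        )
    z = np.stack([s.standardize().as_array() for s in scales])  # P x 20
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    idx = np.array([aa_index[a] for a in seq])
    signals = z[:, idx]  # P x L

    theta = np.empty(params.eta)
    for k in range(1, params.eta + 1):
        diff = signals[:, :-k] - signals[:, k:]  # P x (L - k)
        theta[k - 1] = np.mean(diff ** 2, axis=0).mean()

    freqs = np.bincount(idx, minlength=20) / L
    denom = 1.0 + params.weight * theta.sum()
    return np.concatenate([freqs / denom, params.weight * theta / denom])


def pseaac_feature_names(params: PseAACParams = PseAACParams()) -> list:
    return [f"pseaac.f.{aa}" for aa in AMINO_ACIDS] + [
        f"pseaac.theta.k{k}" for k in range(1, params.eta + 1)
    ]


def dwt_features(
    seq: str,
    params: DWTParams = DWTParams(),
    scales: Sequence[PropertyScale] = DWT_SCALES,
) -> np.ndarray:
    """Wavelet sub-band statistics of per-residue property signals.

    Each standardized property scale maps the sequence to a length-L signal,
    decomposed with a multilevel DWT.  Per property: mean and population SD
    of the raw signal, then max/min/mean/population SD of the coefficients
    in each selected sub-band.  With the defaults (db4, level 4, three
    coarsest bands, three properties) this yields 42 features.
    """
    L = len(seq)
    min_len = params.min_length()
    if L < min_len:
        raise ValueError(
            f"sequence length {L} is below the minimum {min_len} for a level-"
            f"{params.level} {params.wavelet} decomposition; use a lower level"
        )
    names = DWTParams.subband_names(params.level)
    band_index = {name: i for i, name in enumerate(names)}
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    idx = np.array([aa_index[a] for a in seq])

    out = []
    for scale in scales:
        signal = scale.standardize().as_array()[idx]
        out.append(signal.mean())
        out.append(signal.std())
        coeffs = pywt.wavedec(signal, params.wavelet, mode=params.padding, level=params.level)
        for band in params.subbands:
            c = coeffs[band_index[band]]
            out.extend([c.max(), c.min(), c.mean(), c.std()])
    return np.array(out)


def dwt_feature_names(
    params: DWTParams = DWTParams(), scales: Sequence[PropertyScale] = DWT_SCALES
) -> list:
    names = []
    for scale in scales:
        names += [f"dwt.{scale.name}.raw.mean", f"dwt.{scale.name}.raw.sd"]
        for band in params.subbands:
            for stat in ("max", "min", "mean", "sd"):
                names.append(f"dwt.{scale.name}.{band}.{stat}")
    return names
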