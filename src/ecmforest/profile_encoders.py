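"""Profile-derived feature encoders and full feature-vector assembly.

Covers the 156 features computed from externally produced per-protein
profiles — evolutionary PSSM descriptors (80), disorder-track statistics
(8), secondary-structure descriptors (51) and binary functional-domain
indicators (one per vocabulary entry, 17 in the reference configuration) —
plus :func:`encode_all`, which concatenates every requested block in the
canonical order to form the 315-dimensional hybrid vector.
"""

from __future__ import annotations

import dataclasses
from itertools import groupby
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    AMINO_ACIDS,
    SS_STATES,
    DisorderTrack,
    DomainAnnotation,
    FeatureMatrix,
    PSSMProfile,
    ProteinRecord,
    SecondaryStructureTrack,
)
from . import seq_encoders as se

# canonical block order of the assembled vector
BLOCK_ORDER = (
    "ffg",
    "entropy",
    "distribution",
    "transition",
    "pseaac",
    "dwt",
    "pssm",
    "disorder",
    "ssi",
    "fdi",
)

#: blocks computable without a domain vocabulary
VOCABULARY_FREE_BLOCKS = tuple(b for b in BLOCK_ORDER if b != "fdi")

#: block subsets named after the feature categories
SEQUENCE_BLOCKS = ("ffg", "entropy", "distribution", "transition")
PHYSICOCHEMICAL_BLOCKS = ("pseaac", "dwt")
EVOLUTIONARY_BLOCKS = ("pssm",)
STRUCTURAL_BLOCKS = ("disorder", "ssi", "fdi")


@dataclasses.dataclass(frozen=True)
class DomainVocabulary:
    """Ordered list of domain accessions used as binary indicator features.

    The order is fixed at construction and serialized with any model that
    uses it, so indicator columns are stable across runs.
    """

    accessions: tuple
    min_count: int | None = None
    n_positives: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("duplicate accessions in vocabulary")

    def __len__(self) -> int:
        return len(self.accessions)


@dataclasses.dataclass(frozen=True)
class PSSMFeatureParams:
    """Parameters of the evolutionary descriptor.

    ``lag_max`` is the largest sequence separation over which squared
    differences of sigmoid-normalized scores are averaged; with the default
    4, the descriptor has 20 x 4 = 80 components.
    """

    lag_max: int = 4

    def __post_init__(self) -> None:
        if self.lag_max < 1:
            raise ValueError("lag_max must be >= 1")


@dataclasses.dataclass(frozen=True)
class AuxiliaryProfiles:
    """All externally produced per-protein tracks for one protein."""

    pssm: PSSMProfile | None = None
    ss: SecondaryStructureTrack | None = None
    disorder: DisorderTrack | None = None
    domains: frozenset = frozenset()


# ---------------------------------------------------------------------------
# PSSM descriptor
# ---------------------------------------------------------------------------


def pssm_features(
    profile: PSSMProfile, params: PSSMFeatureParams = PSSMFeatureParams()
) -> np.ndarray:
    """Lagged squared-difference descriptor of the normalized profile.

    Raw log-odds scores are squashed elementwise through the sigmoid
    1 / (1 + e^-x); then for each amino-acid column i and lag k,

        theta_i^k = (1 / (L - k)) * sum_j (E_{j,i} - E_{j+k,i})^2.

    Output order is lag-major: all 20 columns at lag 1, then lag 2, ...
    Columns are reported in the canonical alphabet order regardless of the
    source file's column order.
    """
    L = profile.length
    if L <= params.lag_max:
        raise ValueError(f"profile length {L} must exceed lag_max={params.lag_max}")
    # reorder columns into canonical order so features are comparable
    col = {aa: j for j, aa in enumerate(profile.aa_order)}
    order = [col[aa] for aa in AMINO_ACIDS]
    E = 1.0 / (1.0 + np.exp(-profile.scores[:, order]))
    out = np.empty(20 * params.lag_max)
    for k in range(1, params.lag_max + 1):
        diff = E[:-k] - E[k:]
        out[(k - 1) * 20 : k * 20] = np.mean(diff ** 2, axis=0)
    return out


def pssm_feature_names(params: PSSMFeatureParams = PSSMFeatureParams()) -> list:
    return [
        f"pssm.theta.l{k}.{aa}"
        for k in range(1, params.lag_max + 1)
        for aa in AMINO_ACIDS
    ]


# ---------------------------------------------------------------------------
# disorder descriptor
# ---------------------------------------------------------------------------


def _segments(flags: Sequence) -> list:
    """Lengths of maximal runs of equal values, paired with the value."""
    return [(key, sum(1 for _ in grp)) for key, grp in groupby(flags)]


def disorder_features(track: DisorderTrack, threshold: float = 0.5) -> np.ndarray:
    """Eight statistics of the per-residue disorder score track.

    A disorder segment is a maximal run of residues with score >= threshold;
    a non-disorder segment is a maximal run below it.  When a class of
    segment is absent its four length statistics are reported as 0.

    Order: mean, SD (population), #disorder segments, #non-disorder
    segments, min/max disorder-segment length, min/max non-disorder length.
    """
    scores = track.scores
    flags = scores >= threshold
    runs = _segments(flags)
    dis = [n for flag, n in runs if flag]
    non = [n for flag, n in runs if not flag]
    return np.array(
        [
            scores.mean(),
            scores.std(),
            len(dis),
            len(non),
            min(dis) if dis else 0,
            max(dis) if dis else 0,
            min(non) if non else 0,
            max(non) if non else 0,
        ],
        dtype=float,
    )


def disorder_feature_names() -> list:
    return [
        "diso.mean",
        "diso.sd",
        "diso.n_disorder_segments",
        "diso.n_order_segments",
        "diso.min_disorder_len",
        "diso.max_disorder_len",
        "diso.min_order_len",
        "diso.max_order_len",
    ]


# ---------------------------------------------------------------------------
# secondary-structure descriptor
# ---------------------------------------------------------------------------


def _position_spread(positions: np.ndarray) -> float:
    """Population variance of offsets from the first occurrence (0 if < 2)."""
    if positions.size < 2:
        return 0.0
    return float(np.var(positions - positions[0]))


def ss_features(track: SecondaryStructureTrack, seq: str) -> np.ndarray:
    """51 descriptors of the helix/strand/coil state track.

    (i) per-state residue fraction (3); (ii) per-state segment count over
    total segment count (3); (iii) positional spread of each state's
    occurrences, the same variance-of-offsets statistic used for amino
    acids (3); (iv) min/max/mean/population-SD of segment lengths per
    state, 0 when the state is absent (12); (v) joint frequency of
    (functional group, state) over residues, group-major, summing to 1
    (30).
    """
    if len(track) != len(seq):
        raise ValueError(
            f"track length {len(track)} does not match sequence length {len(seq)}"
        )
    states = track.states
    L = len(states)
    arr = np.frombuffer(states.encode("ascii"), dtype=np.uint8)

    fractions = [np.count_nonzero(arr == ord(s)) / L for s in SS_STATES]

    runs = _segments(states)
    total_segments = len(runs)
    seg_lengths = {s: [n for state, n in runs if state == s] for s in SS_STATES}
    seg_shares = [len(seg_lengths[s]) / total_segments for s in SS_STATES]

    spreads = [_position_spread(np.flatnonzero(arr == ord(s))) for s in SS_STATES]

    length_stats = []
    for s in SS_STATES:
        lens = np.array(seg_lengths[s], dtype=float)
        if lens.size:
            length_stats += [lens.min(), lens.max(), lens.mean(), lens.std()]
        else:
            length_stats += [0.0, 0.0, 0.0, 0.0]

    joint = np.zeros((10, 3))
    state_index = {s: i for i, s in enumerate(SS_STATES)}
    for residue, state in zip(seq, states):
        joint[se.GROUP_OF[residue], state_index[state]] += 1
    joint = (joint / L).ravel()  # group-major

    return np.concatenate([fractions, seg_shares, spreads, length_stats, joint])


def ss_feature_names() -> list:
    names = [f"ssi.frac.{s}" for s in SS_STATES]
    names += [f"ssi.seg_share.{s}" for s in SS_STATES]
    names += [f"ssi.spread.{s}" for s in SS_STATES]
    for s in SS_STATES:
        names += [f"ssi.seglen.{s}.{stat}" for stat in ("min", "max", "mean", "sd")]
    for group in se.GROUP_NAMES:
        names += [f"ssi.joint.{group}.{s}" for s in SS_STATES]
    return names


# ---------------------------------------------------------------------------
# functional-domain indicators
# ---------------------------------------------------------------------------


def build_domain_vocabulary(
    annotations: DomainAnnotation,
    positive_ids: Sequence[str],
    min_count: int = 25,
) -> DomainVocabulary:
    """Accessions annotated on at least ``min_count`` distinct positives.

    Sorted by descending positive count, ties broken by accession string,
    so the vocabulary is deterministic.
    """
    if not positive_ids:
        raise ValueError("positive_ids must be non-empty")
    counts: dict = {}
    for pid in set(positive_ids):
        for acc in annotations.domains_of(pid):
            counts[acc] = counts.get(acc, 0) + 1
    chosen = sorted(
        (acc for acc, n in counts.items() if n >= min_count),
        key=lambda acc: (-counts[acc], acc),
    )
    return DomainVocabulary(tuple(chosen), min_count, len(set(positive_ids)))


def fdi_vector(
    protein_id: str, annotations: DomainAnnotation, vocabulary: DomainVocabulary
) -> np.ndarray:
    """Binary presence indicators over the vocabulary for one protein."""
    present = annotations.domains_of(protein_id)
    return np.array([1.0 if acc in present else 0.0 for acc in vocabulary.accessions])


def fdi_feature_names(vocabulary: DomainVocabulary) -> list:
    return [f"fdi.{acc}" for acc in vocabulary.accessions]


# ---------------------------------------------------------------------------
# full-vector assembly
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class EncoderConfig:
    """Which blocks to compute and with what parameters."""

    blocks: tuple = BLOCK_ORDER
    pseaac_params: se.PseAACParams = se.PseAACParams()
    dwt_params: se.DWTParams = se.DWTParams()
    pssm_params: PSSMFeatureParams = PSSMFeatureParams()
    disorder_threshold: float = 0.5
    vocabulary: DomainVocabulary | None = None

    def __post_init__(self) -> None:
        unknown = [b for b in self.blocks if b not in BLOCK_ORDER]
        if unknown:
            raise ValueError(f"unknown block(s) {unknown}")
        # enforce canonical order regardless of how blocks were listed
        ordered = tuple(b for b in BLOCK_ORDER if b in self.blocks)
        object.__setattr__(self, "blocks", ordered)
        if "fdi" in self.blocks and self.vocabulary is None:
            raise ValueError("block 'fdi' requires a domain vocabulary")

    def feature_names(self) -> list:
        names: list = []
        for block in self.blocks:
            if block == "ffg":
                names += se.ffg_feature_names()
            elif block == "entropy":
                names += se.entropy_feature_names()
            elif block == "distribution":
                names += se.distribution_feature_names()
            elif block == "transition":
                names += se.transition_feature_names()
            elif block == "pseaac":
                names += se.pseaac_feature_names(self.pseaac_params)
            elif block == "dwt":
                names += se.dwt_feature_names(self.dwt_params)
            elif block == "pssm":
                names += pssm_feature_names(self.pssm_params)
            elif block == "disorder":
                names += disorder_feature_names()
            elif block == "ssi":
                names += ss_feature_names()
            elif block == "fdi":
                names += fdi_feature_names(self.vocabulary)
        return names


def encode_all(
    record: ProteinRecord,
    profiles: AuxiliaryProfiles,
    config: EncoderConfig | None = None,
    annotations: DomainAnnotation | None = None,
) -> tuple:
    """Assemble the requested feature blocks for one protein.

    Returns ``(feature_names, vector)``.  With the full default
    configuration and a 17-entry vocabulary the vector has
    10 + 2 + 20 + 45 + 40 + 42 + 80 + 8 + 51 + 17 = 315 components.
    """
    seq = record.sequence
    parts: list = []
    for block in config.blocks:
        if block == "ffg":
            parts.append(se.ffg_frequencies(seq))
        elif block == "entropy":
            parts.append(se.shannon_entropies(seq))
        elif block == "distribution":
            parts.append(se.distribution_descriptor(seq))
        elif block == "transition":
            parts.append(se.transition_descriptor(seq))
        elif block == "pseaac":
            parts.append(se.pseaac(seq, config.pseaac_params))
        elif block == "dwt":
            parts.append(se.dwt_features(seq, config.dwt_params))
        elif block == "pssm":
            if profiles.pssm is None:
                raise ValueError(f"{record.id}: block 'pssm' needs a PSSM profile")
            if profiles.pssm.length != len(seq):
                raise ValueError(f"{record.id}: PSSM length differs from sequence length")
            parts.append(pssm_features(profiles.pssm, config.pssm_params))
        elif block == "disorder":
            if profiles.disorder is None:
                raise ValueError(f"{record.id}: block 'disorder' needs a disorder track")
            if len(profiles.disorder) != len(seq):
                raise ValueError(f"{record.id}: disorder track length differs from sequence")
            parts.append(disorder_features(profiles.disorder, config.disorder_threshold))
        elif block == "ssi":
            if profiles.ss is None:
                raise ValueError(f"{record.id}: block 'ssi' needs a secondary-structure track")
            parts.append(ss_features(profiles.ss, seq))
        elif block == "fdi":
            ann = annotations or DomainAnnotation({record.id: frozenset(profiles.domains)})
            parts.append(fdi_vector(record.id, ann, config.vocabulary))
    return config.feature_names(), np.concatenate(parts)


def encode_dataset(
    records: Sequence[ProteinRecord],
    profiles: Mapping[str, AuxiliaryProfiles],
    config: EncoderConfig | None = None,
    labels: Mapping[str, int] | None = None,
) -> FeatureMatrix:
    """Encode many proteins into a :class:`FeatureMatrix`, rows in input order."""
    if config is None:
        config = EncoderConfig(blocks=VOCABULARY_FREE_BLOCKS)
    names = config.feature_names()
    rows = []
    for rec in records:
        prof = profiles.get(rec.id)
        if prof is None:
            raise ValueError(f"no auxiliary profiles for protein {rec.id!r}")
        _, vec = encode_all(rec, prof, config)
        rows.append(vec)
    label_vec = None
    if labels is not None:
        label_vec = np.array([labels[rec.id] for rec in records], dtype=int)
    return FeatureMatrix([r.id for r in records], names, np.vstack(rows), label_vec)
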