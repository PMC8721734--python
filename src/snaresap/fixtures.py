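"""Synthetic sequence / PSSM / feature-matrix generators.

Every pipeline stage is testable without PSI-BLAST or downloads: the
generator emits profiles in the same ASCII dialect the parser reads,
with integer-rounded Gaussian background scores mimicking PSI-BLAST
log-odds output. Class signal is planted in chosen (residue, column)
cells — exactly the coordinates the PSSM-400 encoder sums over — so
feature selection has a known ground-truth informative set: in
positive-class profiles, every position occupied by an informative
cell's residue receives a mean shift of +delta on that cell's column.

``generate_table1_shape`` reproduces the study's class-imbalance regime:
644 / 2,234 positives/negatives for training and 38 / 349 for the
independent test (about 1:3.5 and 1:9).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoding import FeatureMatrix, encode_profiles
from .pssm_io import AA_INDEX, AA_ORDER, PSSMProfile, write_labels, write_pssm

#: Ten default signal-carrying (residue, PSSM column) cells, residues all
#: distinct so the flattened 20*a+b indices never collide.
DEFAULT_INFORMATIVE_CELLS = (
    ("A", "A"),
    ("C", "R"),
    ("D", "N"),
    ("E", "D"),
    ("F", "C"),
    ("G", "Q"),
    ("H", "E"),
    ("I", "G"),
    ("K", "H"),
    ("L", "I"),
)


def cell_feature_index(residue: str, column: str) -> int:
    """Flattened PSSM-400 feature index of a (residue, column) cell."""
    return 20 * AA_INDEX[residue] + AA_INDEX[column]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Background scores are rounded Normal(0, noise_sd); sequence lengths
    are uniform over ``length_range``; residues are uniform over the 20
    canonical letters. ``delta`` is the per-position mean shift applied
    to informative cells in positive-class profiles.
    """

    n_pos: int
    n_neg: int
    length_range: tuple[int, int] = (50, 300)
    informative_cells: tuple = DEFAULT_INFORMATIVE_CELLS
    delta: float = 3.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("sample counts must be non-negative")
        if self.n_pos + self.n_neg == 0:
            raise ValueError("at least one sample is required")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("length_range must satisfy 1 <= min <= max")
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")

    @property
    def informative_features(self) -> np.ndarray:
        """Ground-truth informative PSSM-400 feature indices."""
        return np.array(
            sorted(cell_feature_index(r, c) for r, c in self.informative_cells)
        )


def _one_profile(rng, spec: FixtureSpec, label: int, name: str) -> PSSMProfile:
    lo, hi = spec.length_range
    L = int(rng.integers(lo, hi + 1))
    residues = "".join(AA_ORDER[i] for i in rng.integers(0, 20, size=L))
    scores = rng.normal(0.0, spec.noise_sd, size=(L, 20))
    if label == 1:
        for res, col in spec.informative_cells:
            rows = [p for p, r in enumerate(residues) if r == res]
            scores[rows, AA_INDEX[col]] += spec.delta
    scores = np.rint(scores)
    return PSSMProfile(sequence_id=name, residues=residues, scores=scores)


def generate_profiles(
    spec: FixtureSpec, out_dir=None
) -> tuple[list[PSSMProfile], np.ndarray]:
    """Generate labelled profiles; optionally write them to disk.

    Positives come first (labels +1 then -1). With ``out_dir`` set, one
    ``<id>.pssm`` file per profile plus ``labels.csv`` are written in the
    dialect :func:`snaresap.pssm_io.parse_pssm` reads. Deterministic
    (byte-identical files) given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    profiles: list[PSSMProfile] = []
    labels: list[int] = []
    width = len(str(max(spec.n_pos + spec.n_neg, 1)))
    for i in range(spec.n_pos):
        profiles.append(_one_profile(rng, spec, 1, f"pos_{i:0{width}d}"))
        labels.append(1)
    for i in range(spec.n_neg):
        profiles.append(_one_profile(rng, spec, -1, f"neg_{i:0{width}d}"))
        labels.append(-1)
    labels_arr = np.array(labels, dtype=int)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for p in profiles:
            write_pssm(p, out_dir / f"{p.sequence_id}.pssm")
        write_labels([p.sequence_id for p in profiles], labels_arr, out_dir / "labels.csv")
    return profiles, labels_arr


def generate_feature_matrix(spec: FixtureSpec) -> FeatureMatrix:
    """Profiles encoded straight to a labelled PSSM-400 matrix."""
    profiles, labels = generate_profiles(spec)
    return encode_profiles(profiles, labels)


#: Class counts of the study's train / independent-test splits.
TRAIN_SHAPE = (644, 2234)
TEST_SHAPE = (38, 349)


def generate_table1_shape(
    seed: int = 0, delta: float = 3.0, **kwargs
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Train and test matrices with the study's exact class imbalance.

    Returns (train, test) with 644/2,234 and 38/349 positives/negatives,
    generated end-to-end through profile synthesis and PSSM-400 encoding.
    Extra keyword arguments are forwarded to :class:`FixtureSpec`.
    """
    train_seed, test_seed = (
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(2)
    )
    train = generate_feature_matrix(
        FixtureSpec(*TRAIN_SHAPE, delta=delta, seed=train_seed, **kwargs)
    )
    test = generate_feature_matrix(
        FixtureSpec(*TEST_SHAPE, delta=delta, seed=test_seed, **kwargs)
    )
    return train, test
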