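"""Distance-based residue (DR) feature encoding.

A peptide of length L is encoded as a count vector of dimension
``20 + 400 * d_max``:

* block 0 — occurrences of each of the 20 standard residues, in the
  fixed order A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y;
* block d (1 <= d <= d_max) — occurrences of each ordered residue pair
  (i, j) at exact separation d, i.e. positions t with residue i at t
  and residue j at t + d, laid out row-major over the same ordering.

'X' (unknown residue) occupies a position but contributes to no count,
so for an X-free peptide the block sums are exactly L and L - d.
Counts are raw occurrences, not frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import STANDARD_RESIDUES, SiteWindow

N_RESIDUES = 20
_RESIDUE_INDEX = {aa: k for k, aa in enumerate(STANDARD_RESIDUES)}

VALID_D_MAX = (1, 2, 3)


def dr_dimension(d_max: int) -> int:
    """Feature-vector length for a given maximum pair distance."""
    return N_RESIDUES + N_RESIDUES * N_RESIDUES * d_max


def dr_feature_names(d_max: int) -> list[str]:
    """Names for each DR coordinate: "A", ..., then "AC@d" for the
    ordered pair (A, C) at distance d."""
    names = list(STANDARD_RESIDUES)
    for d in range(1, d_max + 1):
        for a in STANDARD_RESIDUES:
            for b in STANDARD_RESIDUES:
                names.append(f"{a}{b}@{d}")
    return names


@dataclass(frozen=True)
class DRVector:
    """A single DR count vector (integer counts, fixed layout)."""

    d_max: int
    values: np.ndarray

    def block(self, d: int) -> np.ndarray:
        """The length-20 (d=0) or 20x20 row-major (d>=1) slice for distance d."""
        if d == 0:
            return self.values[:N_RESIDUES]
        if not 1 <= d <= self.d_max:
            raise ValueError(f"block distance {d} outside 0..{self.d_max}")
        start = N_RESIDUES + (d - 1) * N_RESIDUES * N_RESIDUES
        return self.values[start : start + N_RESIDUES * N_RESIDUES]


def dr_encode(window_sequence: str, d_max: int) -> DRVector:
    """Encode one peptide as a DR count vector.

    Characters equal to 'X' are skipped in every count; any pair whose
    either member is 'X' contributes nothing.
    """
    if d_max not in VALID_D_MAX:
        raise ValueError(f"d_max must be one of {VALID_D_MAX}, got {d_max}")
    if len(window_sequence) < 1:
        raise ValueError("cannot encode an empty sequence")

    values = np.zeros(dr_dimension(d_max), dtype=np.int64)
    idx = [_RESIDUE_INDEX.get(ch, -1) for ch in window_sequence]  # -1 marks X
    for k in idx:
        if k >= 0:
            values[k] += 1
    L = len(idx)
    for d in range(1, d_max + 1):
        offset = N_RESIDUES + (d - 1) * N_RESIDUES * N_RESIDUES
        for t in range(L - d):
            i, j = idx[t], idx[t + d]
            if i >= 0 and j >= 0:
                values[offset + i * N_RESIDUES + j] += 1
    return DRVector(d_max=d_max, values=values)


@dataclass
class FeatureMatrix:
    """A stack of feature rows with aligned binary labels.

    ``values`` is (n_samples, n_features); ``labels`` is (n_samples,)
    with 1 = carbonylated.  ``synthetic`` flags rows created by SMOTE
    (all-False for encoded or generated data).
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    d_max: int | None = None
    synthetic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.labels = np.asarray(self.labels)
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("values and labels row counts differ")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match columns")
        if self.synthetic is None:
            self.synthetic = np.zeros(self.values.shape[0], dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative)."""
        n1 = int(np.sum(self.labels == 1))
        return n1, self.n_samples - n1

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, d_max: int | None = None) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        if "label" not in df.columns:
            raise ValueError(f"feature table {path} lacks a 'label' column")
        labels = df.pop("label").to_numpy()
        return cls(df.to_numpy(), labels, list(df.columns), d_max=d_max)


def encode_dataset(windows: list[SiteWindow], d_max: int) -> FeatureMatrix:
    """DR-encode every window; rows follow input order, labels carried through.

    Windows that fail to encode are reported together, each with its row
    index, rather than aborting at the first failure.
    """
    if not windows:
        raise ValueError("no windows to encode")
    rows = []
    errors = []
    for r, w in enumerate(windows):
        try:
            rows.append(dr_encode(w.window_sequence, d_max).values)
        except ValueError as exc:
            errors.append(f"row {r} ({w.protein_id}:{w.position}): {exc}")
    if errors:
        raise ValueError("encoding failed:\n" + "\n".join(errors))
    labels = np.array(
        [-1 if w.label is None else int(w.label) for w in windows], dtype=np.int64
    )
    return FeatureMatrix(
        np.vstack(rows), labels, dr_feature_names(d_max), d_max=d_max
    )
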