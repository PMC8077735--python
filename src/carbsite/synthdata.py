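"""Synthetic proteins, site labels and feature blobs for end-to-end
testing without any external database.

The sequence generator emulates the positional signal real
carbonylation data shows: positive sites carry an enrichment of the
motif residue in the few positions immediately upstream of the
modified residue, while negative sites are plain background.  The
strength of that signal is the dial ``enrichment_strength`` (theta):
at 0 the generator is a null (positives and negatives are
distributionally identical); at 1 every enriched position of every
positive site is overwritten.

Per-residue motif layout (upstream offsets that get enriched, and the
residue written there):

    K sites: K at -6..-1      R sites: R at -5..-1
    T sites: T at -3..-2      P sites: no motif

so a P-site generator produces no learnable positional signal
regardless of theta, mirroring the absence of a significant logo for
proline carbonylation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix
from .seqio import SITE_COLUMNS, STANDARD_RESIDUES

#: upstream offsets (relative to the site, negative = N-terminal side)
#: and the residue planted there, per candidate residue type.
MOTIF_LAYOUT: dict[str, tuple[str, tuple[int, ...]]] = {
    "K": ("K", (-6, -5, -4, -3, -2, -1)),
    "R": ("R", (-5, -4, -3, -2, -1)),
    "T": ("T", (-3, -2)),
    "P": ("P", ()),
}

#: flat background over the 20 standard residues (the default keeps
#: tests distribution-agnostic; swap in UNIPROT_FREQUENCIES for more
#: protein-like composition).
UNIFORM_FREQUENCIES = {aa: 1.0 / 20 for aa in STANDARD_RESIDUES}

#: approximate composition of well-annotated proteomes.
UNIPROT_FREQUENCIES = {
    "A": 0.0826, "C": 0.0139, "D": 0.0546, "E": 0.0672, "F": 0.0387,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0475, "Q": 0.0393, "R": 0.0553,
    "S": 0.0665, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}
# renormalize so the preset passes the exact-sum validation
UNIPROT_FREQUENCIES = {
    k: v / sum(UNIPROT_FREQUENCIES.values()) for k, v in UNIPROT_FREQUENCIES.items()
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_proteins: int = 50
    length_range: tuple[int, int] = (200, 400)
    residue: str = "K"
    sites_per_protein: int = 4
    positive_fraction: float = 0.5
    enrichment_strength: float = 0.8
    background_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(UNIFORM_FREQUENCIES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residue not in MOTIF_LAYOUT:
            raise ValueError(f"residue must be one of K, P, R, T; got {self.residue!r}")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        if not 0 <= self.enrichment_strength <= 1:
            raise ValueError("enrichment_strength must be in [0, 1]")
        total = sum(self.background_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {total}, not 1")


def generate(config: GeneratorConfig) -> tuple[str, str]:
    """Generate (FASTA text, site-annotation TSV text).

    Each protein is drawn residue-wise from the background frequencies;
    ``sites_per_protein`` candidate positions (all at least 7 residues
    from the N-terminus, non-adjacent) are overwritten with the target
    residue and annotated.  Sites labeled positive then have each
    enriched upstream position overwritten with the motif residue with
    probability theta.  Fixed seed implies byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list(STANDARD_RESIDUES))
    probs = np.array([config.background_frequencies[a] for a in STANDARD_RESIDUES])
    motif_residue, motif_offsets = MOTIF_LAYOUT[config.residue]
    theta = config.enrichment_strength

    fasta = io.StringIO()
    tsv = io.StringIO()
    tsv.write("\t".join(SITE_COLUMNS) + "\n")
    lo, hi = config.length_range
    for p in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(alphabet, size=length, p=probs)
        # candidate slots: leave room for the longest motif (6 upstream)
        # and keep planted sites at least 2 apart so motifs of adjacent
        # positives cannot overwrite each other's centre.
        slots = np.arange(7, length, 2)  # 0-based positions
        if len(slots) < config.sites_per_protein:
            raise ValueError(
                f"protein length {length} cannot host {config.sites_per_protein} sites"
            )
        planted = np.sort(rng.choice(slots, size=config.sites_per_protein, replace=False))
        labels = (rng.random(config.sites_per_protein) < config.positive_fraction)
        for pos0, positive in zip(planted, labels):
            seq[pos0] = config.residue
            if positive:
                for off in motif_offsets:
                    if rng.random() < theta:
                        seq[pos0 + off] = motif_residue
        pid = f"synth{p:04d}"
        fasta.write(f">{pid}\n{''.join(seq)}\n")
        for pos0, positive in zip(planted, labels):
            tsv.write(f"{pid}\t{pos0 + 1}\t{config.residue}\t{int(positive)}\n")
    return fasta.getvalue(), tsv.getvalue()


def generate_feature_blobs(
    n_per_class: int, dim: int, separation: float, seed: int = 0
) -> FeatureMatrix:
    """Two unit-variance Gaussian classes in `dim` dimensions whose
    means differ by `separation` along each of the first 5 coordinates
    (the rest are pure noise).  Rows: n_per_class positives then
    n_per_class negatives."""
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(seed)
    n_info = min(5, dim)
    X = rng.standard_normal((2 * n_per_class, dim))
    X[:n_per_class, :n_info] += separation
    labels = np.concatenate(
        [np.ones(n_per_class, dtype=np.int64), np.zeros(n_per_class, dtype=np.int64)]
    )
    names = [f"f{j}" for j in range(dim)]
    return FeatureMatrix(X, labels, names, d_max=None)
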