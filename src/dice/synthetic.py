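"""Paired-modality data generator with known ground truth.

The generator emulates the statistical structure the contrastive co-embedding
assumes: proteins live in a shared latent space with cluster organization, and
each modality observes that latent position through its own fixed linear view
plus independent noise. Both views of a protein share the same latent sample,
so individual-level (not just cluster-level) matching signal exists — the
property the zero-shot protocol relies on.

Complementarity models the situation where the two assays carry partly
disjoint information (interaction data resolving some distinctions, imaging
others). A fraction ``c`` of the latent coordinates is split into two exclusive
blocks, each visible to only one modality; on its exclusive block a modality
sees only coarse group-level centers, so at ``c = 1`` neither modality alone
can resolve the full cluster structure while the two together can.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .data_io import GeneSetCollection, ModalityMatrix, PairedDataset, Partition

__all__ = ["SyntheticConfig", "SyntheticResult", "generate", "truth_collections"]


@dataclass
class SyntheticConfig:
    """Knobs of the paired-modality generator.

    Defaults mirror a realistic co-embedding cohort: n=876 proteins in 8
    clusters, 16 latent dimensions observed through two 64-dimensional views,
    moderate noise and well-separated centers.
    """

    n: int = 876
    n_clusters: int = 8
    latent_dim: int = 16
    dim_v: int = 64
    dim_x: int = 64
    noise_sd: float = 0.3
    view_noise_sd: float | None = None  # per-coordinate view noise; see default below
    cluster_sep: float = 4.0
    complementarity: float = 0.5
    scale_x: float = 10.0  # modality-X features on a coarser unit scale than V's
    nested: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.n < self.n_clusters:
            raise ValueError("need n >= n_clusters >= 1")
        if min(self.latent_dim, self.dim_v, self.dim_x) < 2:
            raise ValueError("all dimensions must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.cluster_sep <= 0:
            raise ValueError("cluster_sep must be positive")
        if not 0.0 <= self.complementarity <= 1.0:
            raise ValueError("complementarity must lie in [0, 1]")


class SyntheticResult(NamedTuple):
    dataset: PairedDataset
    truth: Partition
    truth_coarse: Partition


def _view_map(rng: np.random.Generator, out_dim: int, in_dim: int) -> np.ndarray:
    """Random distance-preserving linear view (orthonormal columns when possible)."""
    A = rng.normal(size=(out_dim, in_dim))
    if out_dim >= in_dim:
        Q, _ = np.linalg.qr(A)
        return Q[:, :in_dim]
    return A / np.sqrt(in_dim)


def generate(config: SyntheticConfig) -> SyntheticResult:
    """Draw a paired dataset plus its true (and coarse) cluster partitions.

    Cluster centers: every center coordinate is drawn at a scale such that the
    expected distance between two centers (over all latent dims) equals
    ``cluster_sep``. With complementarity ``c``, ``m = round(c*d/2)`` dims form
    the V-exclusive block (zeroed in X's view) and the next ``m`` the
    X-exclusive block (zeroed in V's view); center values on a modality's
    exclusive block vary only between coarse groups, not between the clusters
    inside a group, so that block carries information the other modality lacks.

    With ``nested=True`` each of the ``n_clusters`` coarse clusters splits into
    two sub-clusters (offset by ``cluster_sep/2``); ``truth`` is then the fine
    partition and ``truth_coarse`` the planted coarse one. Without nesting,
    ``truth_coarse`` pairs consecutive clusters (used as coarse function
    labels downstream).
    """
    rng = np.random.default_rng(config.seed)
    d = config.latent_dim
    K_fine = config.n_clusters * 2 if config.nested else config.n_clusters
    K_coarse = config.n_clusters if config.nested else -(-config.n_clusters // 2)

    m = int(round(config.complementarity * d / 2))
    v_only = np.arange(0, m)                # zeroed in X's view
    x_only = np.arange(m, 2 * m)            # zeroed in V's view
    sigma_c = config.cluster_sep / np.sqrt(2 * d)

    if config.nested:
        coarse_of = np.repeat(np.arange(config.n_clusters), 2)
    else:
        coarse_of = np.arange(K_fine) // 2
    # second, different coarse grouping used for the X-exclusive block
    group_x_of = np.arange(K_fine) % max(1, -(-K_fine // 2))

    centers = rng.normal(scale=sigma_c, size=(K_fine, d))
    # exclusive blocks carry only group-level values
    gv_vals = rng.normal(scale=sigma_c, size=(K_fine, m))
    gx_vals = rng.normal(scale=sigma_c, size=(K_fine, m))
    if m:
        centers[:, v_only] = gv_vals[coarse_of]
        centers[:, x_only] = gx_vals[group_x_of]
    if config.nested:
        # sub-cluster offsets within each coarse cluster
        offs = rng.normal(scale=config.cluster_sep / (2 * np.sqrt(2 * d)), size=(K_fine, d))
        centers = centers + offs

    labels = np.sort(rng.integers(0, K_fine, size=config.n))
    # guarantee every cluster is populated
    labels[:K_fine] = np.arange(K_fine)
    labels = np.sort(labels)

    latent = centers[labels] + rng.normal(scale=config.noise_sd, size=(config.n, d))

    A_v = _view_map(rng, config.dim_v, d)
    A_x = _view_map(rng, config.dim_x, d)
    if m:
        A_v = A_v.copy()
        A_x = A_x.copy()
        A_v[:, x_only] = 0.0
        A_x[:, v_only] = 0.0

    # View noise defaults to noise_sd spread over the output coordinates so the
    # total view-noise energy matches the latent-noise energy instead of
    # growing with the view dimension; encoder embeddings of co-localized
    # proteins are coherent, not noise-dominated.
    sd_v = config.view_noise_sd
    if sd_v is None:
        sd_v = config.noise_sd * np.sqrt(d / config.dim_v)
    sd_x = config.view_noise_sd
    if sd_x is None:
        sd_x = config.noise_sd * np.sqrt(d / config.dim_x)
    V = latent @ A_v.T + rng.normal(scale=sd_v, size=(config.n, config.dim_v))
    # The two encoders live on different unit scales (e.g. random-walk vs CNN
    # features); scale_x applies that asymmetry to modality X. Cosine-based
    # methods are unaffected; naive feature concatenation is dominated by the
    # larger-scale modality, as with real heterogeneous encoders.
    X = config.scale_x * (latent @ A_x.T + rng.normal(scale=sd_x, size=(config.n, config.dim_x)))

    width = len(str(config.n))
    ids = [f"P{i:0{width}d}" for i in range(config.n)]
    dataset = PairedDataset(
        ids,
        ModalityMatrix(ids, V, "modality_v"),
        ModalityMatrix(ids, X, "modality_x"),
    )
    truth = Partition.from_arrays(ids, [int(c) for c in labels])
    truth_coarse = Partition.from_arrays(ids, [int(c) for c in coarse_of[labels]])
    return SyntheticResult(dataset, truth, truth_coarse)


def truth_collections(result: SyntheticResult) -> tuple[GeneSetCollection, GeneSetCollection]:
    """Package the true partitions as gene-set collections (module standard +
    coarse function labels) so the evaluation tools run end-to-end on
    simulated output."""
    def as_sets(part: Partition, prefix: str) -> GeneSetCollection:
        sets: dict[str, set[str]] = {}
        for pid, lab in part.assignment.items():
            sets.setdefault(f"{prefix}{lab:02d}" if isinstance(lab, int) else f"{prefix}{lab}", set()).add(pid)
        return GeneSetCollection({k: frozenset(v) for k, v in sets.items()})

    return as_sets(result.truth, "cluster_"), as_sets(result.truth_coarse, "group_")
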