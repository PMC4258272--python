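"""Synthetic paired resource/test transcriptomes with planted structure.

The generator emulates the statistical shape the ordination method assumes
of immunological genomic data: a handful of well-separated cell classes,
very few replicates per class (duplicates are the norm), disjoint sets of
class-specific marker genes carrying a large between-class effect, and
small within-class Gaussian noise on a log-like scale.  An optional
"knockout" construct adds test samples of one class whose markers lost
their effect — the mutant-versus-wild-type situation the method is meant
to diagnose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import ExpressionMatrix

__all__ = ["SyntheticSpec", "generate_pair"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-marker model.

    Defaults mirror the assumed study conditions: 1000 genes, four helper-T
    classes with duplicate samples, 25 markers per class, an effect of 4
    (log2-like units) on a baseline of 8, and unit noise.
    """

    n_genes: int = 1000
    classes: tuple[str, ...] = ("Th1", "Th2", "Th17", "iTreg")
    markers_per_class: int = 25
    replicates_resource: int = 2
    replicates_test: int = 2
    effect_size: float = 4.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    knockout: tuple[str, float] | None = None  # (class, fraction of markers silenced)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("class labels must be unique")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.baseline_mean < 0:
            raise ValueError("baseline_mean must be non-negative")
        if len(self.classes) * self.markers_per_class > self.n_genes:
            raise ValueError("marker budget exceeds number of genes")
        if self.knockout is not None:
            ko_class, frac = self.knockout
            if ko_class not in self.classes:
                raise ValueError(f"knockout class {ko_class!r} not among classes")
            if not 0 <= frac <= 1:
                raise ValueError("knockout fraction must be in [0, 1]")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(f"gene{i:04d}" for i in range(self.n_genes))

    def marker_genes(self, cls: str) -> tuple[str, ...]:
        """Marker gene ids for a class (disjoint consecutive blocks)."""
        j = self.classes.index(cls)
        lo = j * self.markers_per_class
        return self.gene_ids[lo: lo + self.markers_per_class]


def _simulate(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    replicates: int,
    with_knockout: bool,
) -> ExpressionMatrix:
    k = spec.n_genes
    sample_ids: list[str] = []
    sample_class: list[str] = []
    columns: list[np.ndarray] = []

    def marker_idx(cls: str) -> slice:
        j = spec.classes.index(cls)
        return slice(j * spec.markers_per_class, (j + 1) * spec.markers_per_class)

    for cls in spec.classes:
        for rep in range(replicates):
            mean = np.full(k, spec.baseline_mean)
            mean[marker_idx(cls)] += spec.effect_size
            columns.append(mean + rng.normal(0.0, spec.noise_sd, size=k))
            sample_ids.append(f"{cls}_r{rep + 1}")
            sample_class.append(cls)
    if with_knockout and spec.knockout is not None:
        ko_class, frac = spec.knockout
        n_silenced = int(round(frac * spec.markers_per_class))
        for rep in range(replicates):
            mean = np.full(k, spec.baseline_mean)
            sl = marker_idx(ko_class)
            mean[sl] += spec.effect_size
            mean[sl.start: sl.start + n_silenced] = spec.baseline_mean  # silenced markers
            columns.append(mean + rng.normal(0.0, spec.noise_sd, size=k))
            sample_ids.append(f"{ko_class}-KO_r{rep + 1}")
            sample_class.append(f"{ko_class}-KO")

    values = np.clip(np.column_stack(columns), 0.0, None)
    return ExpressionMatrix(values, spec.gene_ids, tuple(sample_ids), tuple(sample_class))


def generate_pair(spec: SyntheticSpec) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Draw a (resource, test) pair of expression matrices from the spec.

    The resource matrix contains wild-type samples of every class; the test
    matrix contains wild-type samples of every class plus, when
    ``spec.knockout`` is set, knockout replicates of the affected class.
    Fully reproducible given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    resource = _simulate(spec, rng, spec.replicates_resource, with_knockout=False)
    test = _simulate(spec, rng, spec.replicates_test, with_knockout=True)
    return resource, test
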