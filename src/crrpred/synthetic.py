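"""Synthetic regions, sequences, and epigenomic features with planted class structure.

The generator emulates the shape of the real inputs — class-labelled
200-bp regions whose transcription evidence reproduces the intended
activity labels exactly, fixed-length sequences over A/C/G/T with a
position-weight-matrix motif planted in positive-class windows, and
real-valued feature tables with class-conditional location shifts —
with the separability of the sequence channel (embedding probability)
and of the epigenomic channel (effect size) tunable independently.

It does not simulate realistic chromatin tracks, CAGE tag counts, or a
genome assembly; what passing tests show is that the pipeline's methods
behave as designed under controlled class structure, not that they
reach any particular accuracy on real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .encoding import ALPHABET
from .regions import ClassLabel, LabelledRegion, RegionKind, label_region

__all__ = [
    "SyntheticSpec", "SequenceRecord", "benchmark_spec",
    "generate_regions", "generate_sequences", "generate_features",
    "generate_dataset",
]

#: Region kind and evidence sampler per class. Active classes draw
#: evidence strictly above their threshold, inactive classes get 0.
_CLASS_KIND = {
    ClassLabel.AE: RegionKind.ENHANCER, ClassLabel.IE: RegionKind.ENHANCER,
    ClassLabel.AP: RegionKind.PROMOTER, ClassLabel.IP: RegionKind.PROMOTER,
    ClassLabel.AX: RegionKind.EXON, ClassLabel.IX: RegionKind.EXON,
    ClassLabel.UK: RegionKind.UNKNOWN,
}
_ACTIVE_OFFSET = {ClassLabel.AE: 0.0, ClassLabel.AP: 5.0, ClassLabel.AX: 400.0}


def _default_pwm() -> np.ndarray:
    """A sharp 8-mer motif (consensus TGACTCAG), rows = positions."""
    consensus = "TGACTCAG"
    pwm = np.full((len(consensus), 4), 0.05)
    for i, base in enumerate(consensus):
        pwm[i, ALPHABET.index(base)] = 0.85
    return pwm


@dataclass(frozen=True)
class SyntheticSpec:
    class_counts: dict = field(default_factory=dict)  # label -> count
    window_length: int = 200
    pwm: np.ndarray = field(default_factory=_default_pwm)
    embed_prob: dict = field(default_factory=dict)  # label -> probability
    background_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    n_features: int = 8
    n_informative: int = 4
    effect_size: float = 1.0
    positive_labels: frozenset = frozenset({"AE"})
    genome_version: str = "hg19"
    cell_line: str = "synthetic"
    chrom: str = "chrS"
    chrom_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.class_counts.values()):
            raise ValueError("class counts must be non-negative")
        pwm = np.asarray(self.pwm, dtype=float)
        if not (6 <= len(pwm) <= 12):
            raise ValueError("motif length must be 6-12")
        if not np.allclose(pwm.sum(axis=1), 1.0):
            raise ValueError("PWM rows must sum to 1")
        if not np.isclose(sum(self.background_freqs), 1.0):
            raise ValueError("background frequencies must sum to 1")
        probs = list(self.embed_prob.values())
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("embedding probabilities must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative outside [0, n_features]")
        object.__setattr__(self, "pwm", pwm)

    @property
    def n_total(self) -> int:
        return sum(self.class_counts.values())


def benchmark_spec(
    n_total: int = 2000,
    imbalance_ratio: float = 20.0,
    effect_size: float = 1.0,
    embed_prob: float = 1.0,
    seed: int = 0,
    **overrides,
) -> SyntheticSpec:
    """The default benchmark condition: an AE-vs-IE-style task.

    A minority of active enhancers against a 20:1 majority of inactive
    ones, 200-bp windows, an 8-mer motif planted in every active
    sequence, and a unit location shift on half of 8 epigenomic
    features.
    """
    minority = max(2, int(round(n_total / (1.0 + imbalance_ratio))))
    spec = SyntheticSpec(
        class_counts={"AE": minority, "IE": n_total - minority},
        embed_prob={"AE": embed_prob},
        effect_size=effect_size,
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def _rng_for(spec: SyntheticSpec, stream: str) -> np.random.Generator:
    """Independent deterministic stream per generator stage."""
    streams = {"regions": 0, "sequences": 1, "features": 2}
    return np.random.default_rng(
        np.random.SeedSequence(spec.seed).spawn(3)[streams[stream]]
    )


def generate_regions(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> list[LabelledRegion]:
    """Non-overlapping windows on a synthetic chromosome, labels exact.

    Evidence is drawn per class — active classes log-normally above
    their activity threshold, inactive classes exactly 0 — so that
    re-applying the labeling rules recovers the intended class of every
    region.
    """
    rng = rng or _rng_for(spec, "regions")
    n = spec.n_total
    needed = n * spec.window_length
    limit = spec.chrom_length if spec.chrom_length is not None else needed
    if needed > limit:
        raise ValueError(
            f"{n} windows of {spec.window_length} bp overflow "
            f"chromosome length {limit}"
        )
    regions = []
    pos = 0
    for label_name in sorted(spec.class_counts):
        label = ClassLabel(label_name)
        kind = _CLASS_KIND[label]
        for _ in range(spec.class_counts[label_name]):
            if kind is RegionKind.UNKNOWN:
                evidence = None
            elif label in _ACTIVE_OFFSET:
                evidence = _ACTIVE_OFFSET[label] + float(rng.lognormal(0.0, 1.0))
            else:
                evidence = 0.0
            start = pos
            pos += spec.window_length
            regions.append(
                LabelledRegion(
                    chrom=spec.chrom, start=start, end=start + spec.window_length,
                    cell_line=spec.cell_line, kind=kind, evidence=evidence,
                    label=label_region(kind, evidence, spec.genome_version),
                )
            )
    return regions


@dataclass(frozen=True)
class SequenceRecord:
    sequence: str
    label: str
    motif_start: int  # -1 when no motif was planted


def generate_sequences(
    labels,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> list[SequenceRecord]:
    """Background sequences with class-dependent planted motifs.

    Each sequence is i.i.d. from the background nucleotide frequencies;
    with the class's embedding probability one motif instance sampled
    from the PWM overwrites a uniformly placed window. The planting
    position is recorded for test introspection.
    """
    rng = rng or _rng_for(spec, "sequences")
    mlen = len(spec.pwm)
    if mlen > spec.window_length:
        raise ValueError("motif longer than sequence window")
    bases = np.array(list(ALPHABET))
    records = []
    for label in labels:
        label = ClassLabel(label).value
        seq = rng.choice(bases, size=spec.window_length, p=spec.background_freqs)
        start = -1
        if rng.random() < spec.embed_prob.get(label, 0.0):
            start = int(rng.integers(0, spec.window_length - mlen + 1))
            for i in range(mlen):
                seq[start + i] = bases[rng.choice(4, p=spec.pwm[i])]
        records.append(SequenceRecord("".join(seq), label, start))
    return records


def generate_features(
    labels,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Class-conditional Gaussian feature table.

    Negative-class rows are N(0,1) everywhere; positive-class rows are
    shifted by the effect size (in within-class standard deviations) on
    the informative feature subset. Remaining features are pure noise
    for both classes. Columns are named track_00, track_01, ... to
    mirror the lexicographic track ordering of the real-data path.
    """
    rng = rng or _rng_for(spec, "features")
    labels = [ClassLabel(l).value for l in labels]
    n = len(labels)
    x = rng.standard_normal((n, spec.n_features))
    positive = np.array([l in spec.positive_labels for l in labels])
    x[np.ix_(positive, np.arange(spec.n_informative))] += spec.effect_size
    cols = [f"track_{j:02d}" for j in range(spec.n_features)]
    return pd.DataFrame(x, columns=cols)


def generate_dataset(spec: SyntheticSpec):
    """Regions, sequences, features, and the binary task labels.

    Returns ``(regions, sequences, features, y)`` where y marks
    membership of the spec's positive label set. All three channels are
    generated from independent deterministic substreams of the spec
    seed.
    """
    regions = generate_regions(spec)
    labels = [r.label.value for r in regions]
    sequences = generate_sequences(labels, spec)
    features = generate_features(labels, spec)
    y = np.array([l in spec.positive_labels for l in labels], dtype=int)
    return regions, sequences, features, y
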