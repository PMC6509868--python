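"""Probe sequences as multiple-instance bags of one-hot encoded windows.

A protein-binding-microarray probe is treated as a *bag*; every fixed-width
window obtained by sliding a ``c``-bp window along the probe in steps of
``s`` bp is an *instance* of that bag. A probe of length ``L >= c`` yields
exactly ``floor((L - c) / s) + 1`` instances. Each window is mapped to a
binary feature vector of length ``4 * c`` by concatenating one-hot codes for
its nucleotides, using the fixed alphabet order A, T, C, G:

    A -> (1, 0, 0, 0)   T -> (0, 1, 0, 0)
    C -> (0, 0, 1, 0)   G -> (0, 0, 0, 1)

The bag label ``Y_I`` follows the multiple-instance convention: a bag is
positive iff at least one of its windows is a true binding site; every
window of a negative bag is a negative example.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: Fixed nucleotide order used by the one-hot encoding and by every PWM row.
ALPHABET: tuple[str, ...] = ("A", "T", "C", "G")

_INDEX = {base: i for i, base in enumerate(ALPHABET)}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def instance_count(length: int, window: int, step: int) -> int:
    """Number of full windows in a sequence: ``floor((L - c) / s) + 1``."""
    if length < window:
        raise ValueError(
            f"probe shorter than window: length {length} < window {window}"
        )
    return (length - window) // step + 1


def reverse_complement(sequence: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(sequence))


@dataclass(frozen=True)
class BagConfig:
    """Sliding-window parameters for bag construction.

    Parameters
    ----------
    window : int
        Window width ``c`` in bp; the putative binding-site length.
    step : int
        Step ``s`` in bp between consecutive window starts.
    probe_length : int
        Informational: the expected probe length ``l`` (35 bp for the
        variable region of a standard PBM probe).
    strand_mode : str
        ``"forward-only"`` scans the given strand only; with
        ``"with-reverse-complement"`` each window's reverse complement is
        appended as an extra instance of the same bag.
    """

    window: int = 10
    step: int = 1
    probe_length: int = 35
    strand_mode: str = "forward-only"
    alphabet: tuple[str, ...] = ALPHABET

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.strand_mode not in ("forward-only", "with-reverse-complement"):
            raise ValueError(f"unknown strand_mode: {self.strand_mode!r}")
        if tuple(self.alphabet) != ALPHABET:
            raise ValueError("alphabet order is fixed to (A, T, C, G)")

    @property
    def feature_dim(self) -> int:
        """Length of an encoded instance vector (``4 * window``)."""
        return 4 * self.window


@dataclass(frozen=True)
class Instance:
    """One window of a probe: ``sequence == probe[start : start + c]``."""

    sequence: str
    start: int
    bag_id: str
    label: int | None = None  # -1, +1 or None (unknown)
    strand: str = "+"


@dataclass(frozen=True)
class EncodedInstance:
    """One-hot feature vector of an :class:`Instance` (length ``4 * c``)."""

    vector: np.ndarray
    instance: Instance | None = None


@dataclass
class LabeledBag:
    """A probe and its windows; ``label`` is ``Y_I`` (None = unlabeled)."""

    bag_id: str
    instances: list[Instance]
    label: int | None

    def __post_init__(self) -> None:
        if not self.instances:
            raise ValueError("a bag needs at least one instance")
        if self.label not in (-1, 1, None):
            raise ValueError("bag label must be -1, +1 or None")

    @property
    def n_instances(self) -> int:
        return len(self.instances)


def _validate_sequence(probe: str) -> str:
    probe = probe.upper()
    for pos, ch in enumerate(probe):
        if ch not in _INDEX:
            raise ValueError(
                f"non-ACGT symbol {ch!r} at position {pos}; ambiguity codes "
                "are rejected, not imputed"
            )
    return probe


def make_bag(
    probe: str,
    config: BagConfig,
    label: int | None,
    bag_id: str = "probe",
) -> LabeledBag:
    """Slide the window along ``probe`` and collect every full window.

    Windows are enumerated left to right at starts ``0, s, 2s, ...`` using
    0-based half-open coordinates; trailing bases not covered by a full
    window are dropped. Lowercase input is uppercased; any non-ACGT symbol
    raises a :class:`ValueError` naming the character and position.
    """
    probe = _validate_sequence(probe)
    c, s = config.window, config.step
    n = instance_count(len(probe), c, s)
    instances = [
        Instance(sequence=probe[i * s : i * s + c], start=i * s, bag_id=bag_id)
        for i in range(n)
    ]
    if config.strand_mode == "with-reverse-complement":
        instances += [
            Instance(
                sequence=reverse_complement(inst.sequence),
                start=inst.start,
                bag_id=bag_id,
                strand="-",
            )
            for inst in instances
        ]
    return LabeledBag(bag_id=bag_id, instances=instances, label=label)


def encode_sequence(sequence: str) -> np.ndarray:
    """One-hot encode a sequence into a flat ``4 * len`` float vector."""
    sequence = _validate_sequence(sequence)
    vec = np.zeros(4 * len(sequence))
    for j, base in enumerate(sequence):
        vec[4 * j + _INDEX[base]] = 1.0
    return vec


def encode_instance(inst: Instance, config: BagConfig) -> EncodedInstance:
    if len(inst.sequence) != config.window:
        raise ValueError(
            f"instance length {len(inst.sequence)} != window {config.window}"
        )
    return EncodedInstance(vector=encode_sequence(inst.sequence), instance=inst)


def decode_instance(
    encoded: EncodedInstance | np.ndarray, config: BagConfig
) -> str:
    """Invert :func:`encode_instance` under the fixed alphabet order."""
    vec = encoded.vector if isinstance(encoded, EncodedInstance) else np.asarray(encoded)
    if vec.shape != (config.feature_dim,):
        raise ValueError(
            f"vector length {vec.size} != 4 * window = {config.feature_dim}"
        )
    bases = []
    for j in range(config.window):
        block = vec[4 * j : 4 * j + 4]
        hot = np.flatnonzero(block == 1.0)
        if hot.size != 1 or not np.all((block == 0.0) | (block == 1.0)):
            raise ValueError(
                f"malformed one-hot block at position {j}: {block.tolist()}"
            )
        bases.append(ALPHABET[hot[0]])
    return "".join(bases)


def encode_bag(bag: LabeledBag, config: BagConfig) -> np.ndarray:
    """Stack a bag's instances into a ``(k, 4c)`` feature matrix."""
    return np.stack(
        [encode_instance(inst, config).vector for inst in bag.instances]
    )


def bags_from_sequences(
    sequences: Iterable[str],
    config: BagConfig,
    label: int | None,
    ids: Sequence[str] | None = None,
    id_prefix: str = "probe",
) -> list[LabeledBag]:
    """Build one bag per sequence, all with the same label."""
    sequences = list(sequences)
    if ids is None:
        width = max(1, len(str(len(sequences))))
        ids = [f"{id_prefix}{i:0{width}d}" for i in range(len(sequences))]
    return [
        make_bag(seq, config, label, bag_id=str(bid))
        for seq, bid in zip(sequences, ids, strict=True)
    ]
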