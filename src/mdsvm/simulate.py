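"""Planted-motif synthetic probe generator.

Emulates the variable region of a PBM probe set with known ground truth:
positive probes are i.i.d. background sequence with exactly one binding
site sampled from a PWM planted at a fixed or uniformly random offset;
negative probes are pure background, rejection-resampled so the motif's
consensus never appears exactly. Binding intensities are drawn from two
non-overlapping uniform bands (negatives in [0, 1], positives in
[1 + gap, 2 + gap]) so that intensity ranking recovers the planted labels
whenever ``intensity_gap > 0`` — downstream steps only use ranks, so the
band shape is immaterial.

Every dataset carries its planted PWM and per-probe offsets, which makes
motif-recovery assertions possible without any external array data.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np
from scipy.special import psi

from .bags import ALPHABET
from .motif import Pwm, information_content

_MAX_ATTEMPTS = 100_000
_UNIFORM = np.full(4, 0.25)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic probe table.

    ``plant_position`` is either an integer offset (every positive probe
    gets its site at that offset) or ``"uniform"`` (offset drawn uniformly
    over all full-window positions). ``motif=None`` samples a PWM at
    ``motif_ic_target`` bits per column.
    """

    n_pos: int = 200
    n_neg: int = 200
    probe_length: int = 35
    motif_length: int = 10
    motif: Pwm | None = None
    motif_ic_target: float = 1.5
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    plant_position: Union[int, str] = "uniform"
    intensity_gap: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        length = self.motif.length if self.motif is not None else self.motif_length
        if self.probe_length < length:
            raise ValueError("probe_length must be >= motif length")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg < 0) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be a length-4 probability vector")
        if isinstance(self.plant_position, int):
            if not 0 <= self.plant_position <= self.probe_length - length:
                raise ValueError("plant_position offset out of range")
        elif self.plant_position != "uniform":
            raise ValueError("plant_position must be an offset or 'uniform'")
        if self.intensity_gap <= 0:
            raise ValueError("intensity_gap must be > 0")


@dataclass
class SyntheticDataset:
    """Probe table plus the ground truth it was generated from."""

    sequences: list[str]
    intensities: np.ndarray
    labels: np.ndarray  # +1 / -1 per probe
    planted_offsets: np.ndarray  # site offset for positives, -1 for negatives
    pwm: Pwm
    config: SimConfig

    def probe_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sequence": self.sequences,
                "intensity": self.intensities,
                "label": self.labels,
                "planted_offset": self.planted_offsets,
            }
        )


def _expected_ic(alpha: float) -> float:
    # Mean information content (bits) of a symmetric Dirichlet(alpha) column:
    # E[H] = psi(4a + 1) - psi(a + 1) nats.
    return 2.0 - (psi(4 * alpha + 1) - psi(alpha + 1)) / math.log(2)


def _alpha_for_ic(ic_target: float) -> float:
    lo, hi = 1e-6, 80.0
    if ic_target >= _expected_ic(lo):
        return lo
    if ic_target <= _expected_ic(hi):
        return hi
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if _expected_ic(mid) > ic_target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def sample_pwm(
    length: int,
    ic_target: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    ic_window: float = 0.2,
) -> Pwm:
    """Draw a random PWM whose columns hit ``ic_target`` bits (+/- window).

    Columns are Dirichlet draws with the concentration matched to the
    target's expected entropy, accepted only when the realised column IC
    lies within ``ic_window`` bits of the target.
    """
    if not 0 < ic_target <= 2:
        raise ValueError("ic_target must lie in (0, 2] bits")
    if rng is None:
        rng = np.random.default_rng(seed)
    alpha = _alpha_for_ic(ic_target)
    lo, hi = max(0.0, ic_target - ic_window), min(2.0, ic_target + ic_window)
    columns = []
    for _ in range(length):
        for attempt in range(10_000):
            col = rng.dirichlet(np.full(4, alpha))
            ic = 2.0 + float(np.sum(col[col > 0] * np.log2(col[col > 0])))
            if lo <= ic <= hi:
                columns.append(col)
                break
        else:
            raise ValueError(
                f"could not reach an IC of {ic_target} bits per column; "
                "the target may be infeasible"
            )
    return Pwm(probs=np.stack(columns, axis=1))


def _sample_background(rng: np.random.Generator, length: int, bg: np.ndarray) -> str:
    draws = rng.choice(4, size=length, p=bg)
    return "".join(ALPHABET[i] for i in draws)


def _sample_site(rng: np.random.Generator, pwm: Pwm) -> str:
    return "".join(
        ALPHABET[rng.choice(4, p=pwm.probs[:, j])] for j in range(pwm.length)
    )


def _occurrences(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i == -1:
            return hits
        hits.append(i)
        start = i + 1


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate a fully reproducible planted-motif probe table."""
    rng = np.random.default_rng(config.seed)
    pwm = config.motif or sample_pwm(
        config.motif_length, config.motif_ic_target, rng=rng
    )
    bg = np.asarray(config.background, dtype=float)
    consensus = pwm.consensus
    L, l = pwm.length, config.probe_length
    gap = config.intensity_gap

    sequences: list[str] = []
    offsets: list[int] = []
    for _ in range(config.n_pos):
        for attempt in range(_MAX_ATTEMPTS):
            if config.plant_position == "uniform":
                offset = int(rng.integers(0, l - L + 1))
            else:
                offset = int(config.plant_position)
            backbone = _sample_background(rng, l, bg)
            site = _sample_site(rng, pwm)
            seq = backbone[:offset] + site + backbone[offset + L :]
            # Exactly one planted occurrence: the consensus must not appear
            # anywhere other than (possibly) the planted offset itself.
            if all(hit == offset for hit in _occurrences(seq, consensus)):
                sequences.append(seq)
                offsets.append(offset)
                break
        else:
            raise ValueError(
                "rejection sampling exhausted; use a longer probe or a "
                "weaker motif"
            )
    for _ in range(config.n_neg):
        for attempt in range(_MAX_ATTEMPTS):
            seq = _sample_background(rng, l, bg)
            if consensus not in seq:
                sequences.append(seq)
                offsets.append(-1)
                break
        else:
            raise ValueError(
                "rejection sampling exhausted; use a longer probe or a "
                "weaker motif"
            )

    intensities = np.concatenate(
        [
            rng.uniform(1.0 + gap, 2.0 + gap, size=config.n_pos),
            rng.uniform(0.0, 1.0, size=config.n_neg),
        ]
    )
    labels = np.concatenate(
        [np.ones(config.n_pos, dtype=int), -np.ones(config.n_neg, dtype=int)]
    )
    return SyntheticDataset(
        sequences=sequences,
        intensities=intensities,
        labels=labels,
        planted_offsets=np.asarray(offsets),
        pwm=pwm,
        config=config,
    )


def write_truth(dataset: SyntheticDataset, pfm_path: str | os.PathLike, offsets_path: str | os.PathLike) -> None:
    """Write the planted PFM (JASPAR) and the per-probe offsets (TSV)."""
    from .motif import write_jaspar

    write_jaspar(dataset.pwm, pfm_path, name="planted")
    with open(offsets_path, "w") as handle:
        handle.write("probe\tlabel\tplanted_offset\n")
        for i, (label, off) in enumerate(zip(dataset.labels, dataset.planted_offsets)):
            handle.write(f"probe{i}\t{label:+d}\t{off}\n")
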