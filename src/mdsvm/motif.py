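"""Position weight matrices: construction, log-odds scoring, logos.

A PWM is a 4 x L column-stochastic matrix ``p_j(x)`` giving the
probability of each nucleotide at each binding-site position, with rows in
the fixed alphabet order A, T, C, G. A sequence ``x`` of length L is
scored against a background distribution ``p_bg`` by the log-odds sum

    S(x) = sum_{j=1}^{L} log2( p_j(x_j) / p_bg(x_j) )

and a column's conservation is its information content
``2 + sum_x p log2 p`` bits (0 for a uniform column, 2 for a fully
conserved one); a sequence logo draws letters of height
``p_j(x) * IC_j``.

``extract_motif`` is the final step of the discovery pipeline: it pools
the witness windows of every bag a trained MIL model predicts positive and
estimates the PWM from their letter counts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .bags import ALPHABET, LabeledBag, _INDEX
from .mil import MilSvmModel, bag_score, predict_bag

_UNIFORM = np.full(4, 0.25)

#: Row order of the JASPAR PFM format (differs from the internal A,T,C,G).
_JASPAR_ORDER = ("A", "C", "G", "T")


@dataclass
class Pwm:
    """Column-stochastic 4 x L nucleotide probability matrix."""

    probs: np.ndarray  # (4, L), rows in ALPHABET order
    background: np.ndarray = field(default_factory=lambda: _UNIFORM.copy())
    pseudocount: float = 0.0
    source_count: int = 0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("probs must be a 4 x L matrix")
        if np.any(self.probs < 0) or np.any(self.background < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("each PWM column must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        """Most probable letter per column; ties favour A > T > C > G order."""
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=0))


@dataclass
class LogoMatrix:
    """Letter heights (bits) and per-column information content."""

    heights: np.ndarray  # (4, L)
    column_ic: np.ndarray  # (L,)


def build_pwm(
    instances: list[str],
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> Pwm:
    """Estimate a PWM from equal-length site sequences.

    ``p_j(x) = (count_j(x) + pseudocount) / (N + 4 * pseudocount)``.
    """
    if not instances:
        raise ValueError("need at least one instance to build a PWM")
    length = len(instances[0])
    counts = np.zeros((4, length))
    for seq in instances:
        if len(seq) != length:
            raise ValueError(
                f"ragged instance lengths: {len(seq)} != {length}"
            )
        for j, base in enumerate(seq.upper()):
            if base not in _INDEX:
                raise ValueError(f"non-ACGT symbol {base!r} in instance")
            counts[_INDEX[base], j] += 1
    probs = (counts + pseudocount) / (len(instances) + 4 * pseudocount)
    return Pwm(
        probs=probs,
        background=_UNIFORM.copy() if background is None else np.asarray(background, float),
        pseudocount=pseudocount,
        source_count=len(instances),
    )


def log_odds_score(pwm: Pwm, x: str) -> float:
    """``S(x) = sum_j log2(p_j(x_j) / p_bg(x_j))`` in bits."""
    x = x.upper()
    if len(x) != pwm.length:
        raise ValueError(f"sequence length {len(x)} != motif length {pwm.length}")
    score = 0.0
    for j, base in enumerate(x):
        if base not in _INDEX:
            raise ValueError(f"non-ACGT symbol {base!r} at position {j}")
        p = pwm.probs[_INDEX[base], j]
        if p == 0.0:
            raise ValueError(
                f"zero probability for {base!r} at position {j}; "
                "build the PWM with a pseudocount > 0"
            )
        score += np.log2(p / pwm.background[_INDEX[base]])
    return float(score)


def scan_best_site(pwm: Pwm, probe: str) -> tuple[float, int]:
    """Best log-odds window over the probe; lowest start wins ties."""
    probe = probe.upper()
    if len(probe) < pwm.length:
        raise ValueError(
            f"probe length {len(probe)} < motif length {pwm.length}"
        )
    best_score, best_start = -np.inf, 0
    for start in range(len(probe) - pwm.length + 1):
        score = log_odds_score(pwm, probe[start : start + pwm.length])
        if score > best_score:
            best_score, best_start = score, start
    return float(best_score), best_start


def information_content(pwm: Pwm) -> LogoMatrix:
    """Per-column IC (bits) and logo letter heights ``p * IC``."""
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    column_ic = 2.0 + plogp.sum(axis=0)
    column_ic = np.clip(column_ic, 0.0, 2.0)  # guard round-off at the edges
    return LogoMatrix(heights=p * column_ic, column_ic=column_ic)


def extract_motif(
    model: MilSvmModel,
    bags: list[LabeledBag],
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> tuple[Pwm, list[str]]:
    """PWM from the witness windows of bags the model predicts positive.

    For every bag with a positive predicted label the highest-scoring
    instance (the witness) is collected; the PWM is built from those
    windows. Returns the PWM and the witness sequences for audit.
    """
    witnesses: list[str] = []
    for bag in bags:
        if predict_bag(model, bag) == 1:
            _, idx = bag_score(model, bag)
            witnesses.append(bag.instances[idx].sequence)
    if not witnesses:
        raise ValueError("no positive predictions; cannot build PWM")
    return build_pwm(witnesses, pseudocount=pseudocount, background=background), witnesses


# --------------------------------------------------------------------------
# Motif file formats.


def write_jaspar(pwm: Pwm, path: str | os.PathLike, name: str = "motif") -> None:
    """Write a JASPAR PFM (counts matrix, rows A/C/G/T)."""
    n = pwm.source_count if pwm.source_count > 0 else 100
    counts = pwm.probs * n
    with open(path, "w") as handle:
        handle.write(f">{name}\n")
        for base in _JASPAR_ORDER:
            row = counts[_INDEX[base]]
            cells = "  ".join(f"{v:.2f}" for v in row)
            handle.write(f"{base}  [ {cells} ]\n")


def read_jaspar(path: str | os.PathLike, pseudocount: float = 0.0) -> Pwm:
    """Read a JASPAR PFM and normalise counts to probabilities."""
    rows: dict[str, np.ndarray] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            base, rest = line[0].upper(), line[1:]
            if base not in _INDEX:
                raise ValueError(f"{path}: unexpected PFM row {line!r}")
            rest = rest.replace("[", " ").replace("]", " ")
            rows[base] = np.asarray([float(v) for v in rest.split()])
    if sorted(rows) != sorted("ACGT"):
        raise ValueError(f"{path}: PFM must have exactly the rows A, C, G, T")
    counts = np.stack([rows[b] for b in ALPHABET])
    totals = counts.sum(axis=0) + 4 * pseudocount
    probs = (counts + pseudocount) / totals
    return Pwm(
        probs=probs,
        pseudocount=pseudocount,
        source_count=int(round(counts.sum(axis=0).max())),
    )


def write_meme(pwm: Pwm, path: str | os.PathLike, name: str = "motif") -> None:
    """Write a MEME minimal motif file (letter-probability matrix)."""
    bg = pwm.background
    with open(path, "w") as handle:
        handle.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        handle.write(
            "Background letter frequencies\n"
            f"A {bg[_INDEX['A']]:.5f} C {bg[_INDEX['C']]:.5f} "
            f"G {bg[_INDEX['G']]:.5f} T {bg[_INDEX['T']]:.5f}\n\n"
        )
        handle.write(f"MOTIF {name}\n")
        handle.write(
            f"letter-probability matrix: alphabet= 4 w= {pwm.length} "
            f"nsites= {max(pwm.source_count, 1)}\n"
        )
        for j in range(pwm.length):
            handle.write(
                "  ".join(
                    f"{pwm.probs[_INDEX[b], j]:.6f}" for b in ("A", "C", "G", "T")
                )
                + "\n"
            )


def write_logo_heights(pwm: Pwm, path: str | os.PathLike) -> None:
    """Tab-delimited letter-height matrix (bits) plus the per-column IC."""
    logo = information_content(pwm)
    with open(path, "w") as handle:
        handle.write("position\t" + "\t".join(ALPHABET) + "\tIC\n")
        for j in range(pwm.length):
            heights = "\t".join(f"{logo.heights[i, j]:.6f}" for i in range(4))
            handle.write(f"{j}\t{heights}\t{logo.column_ic[j]:.6f}\n")


def render_logo(pwm: Pwm, path: str | os.PathLike, title: str = "") -> None:
    """Render a simple stacked-letter sequence logo to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
    logo = information_content(pwm)
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * pwm.length), 2.5))
    font = FontProperties(family="DejaVu Sans", weight="bold")
    for j in range(pwm.length):
        order = np.argsort(logo.heights[:, j])  # small letters at the bottom
        y = 0.0
        for i in order:
            h = logo.heights[i, j]
            if h <= 1e-3:
                continue
            tp = TextPath((0, 0), ALPHABET[i], size=1.0, prop=font)
            bb = tp.get_extents()
            transform = (
                Affine2D()
                .translate(-bb.x0, -bb.y0)
                .scale(0.9 / bb.width, h / bb.height)
                .translate(j + 0.05, y)
            )
            ax.add_patch(
                PathPatch(transform.transform_path(tp), color=colors[ALPHABET[i]], lw=0)
            )
            y += h
    ax.set_xlim(0, pwm.length)
    ax.set_ylim(0, 2)
    ax.set_xticks(np.arange(pwm.length) + 0.5)
    ax.set_xticklabels(np.arange(1, pwm.length + 1))
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(str(path), dpi=150)
    plt.close(fig)
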