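import numpy as np
import pytest

from mdsvm import (
    BagConfig,
    Instance,
    LabeledBag,
    TrainingConfig,
    bags_from_sequences,
    make_bag,
)

BASES = list("ATCG")


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def mutate(sequence: str, rng: np.random.Generator, k: int) -> str:
    out = list(sequence)
    for pos in rng.choice(len(out), size=k, replace=False):
        out[pos] = rng.choice([b for b in BASES if b != out[pos]])
    return "".join(out)


def planted_toy(seed: int, window: int = 10, n_neg: int = 3):
    """A tiny MIL problem with a shared planted motif instance per positive bag.

    Every positive bag holds 1-3 sliding windows of random background with
    one window replaced by a (possibly single-mutation) copy of a common
    random motif; negative bags are pure background. Returns the bags and
    the planted witness index per positive bag.
    """
    rng = np.random.default_rng(seed)
    cfg = BagConfig(window=window)
    motif = random_sequence(rng, window)
    planted: dict[str, int] = {}

    def positive_bag(bag_id: str) -> LabeledBag:
        n = int(rng.integers(1, 4))
        bag = make_bag(random_sequence(rng, window + n - 1), cfg, 1, bag_id=bag_id)
        k = int(rng.integers(0, 2))
        site = mutate(motif, rng, k) if k else motif
        idx = int(rng.integers(0, n))
        old = bag.instances[idx]
        bag.instances[idx] = Instance(site, old.start, bag_id)
        planted[bag_id] = idx
        return bag

    def negative_bag(bag_id: str) -> LabeledBag:
        n = int(rng.integers(1, 4))
        return make_bag(random_sequence(rng, window + n - 1), cfg, -1, bag_id=bag_id)

    bags = [positive_bag(f"p{i}") for i in range(int(rng.integers(1, 4)))]
    bags += [negative_bag(f"n{i}") for i in range(n_neg)]
    return bags, planted, cfg


@pytest.fixture(scope="session")
def bag_config() -> BagConfig:
    return BagConfig()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_training_problem():
    """40 probes with a strong planted motif: fast, cleanly separable."""
    from mdsvm import SimConfig, generate_dataset

    dataset = generate_dataset(
        SimConfig(n_pos=20, n_neg=20, motif_ic_target=1.8, seed=7)
    )
    cfg = BagConfig()
    pos = bags_from_sequences(dataset.sequences[:20], cfg, 1, id_prefix="p")
    neg = bags_from_sequences(dataset.sequences[20:], cfg, -1, id_prefix="n")
    return dataset, pos, neg, cfg
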