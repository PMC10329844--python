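import numpy as np
import pandas as pd
import pytest

from roninloops.synthetic import GenomeModel, SyntheticConfig


def make_peaks(positions, intensities, chrom="chr1", width=2000):
    """Non-overlapping peak frame from centre positions."""
    rows = [(chrom, p - width // 2, p + width // 2, float(w), f"P{i:05d}")
            for i, (p, w) in enumerate(zip(positions, intensities))]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "intensity",
                                       "peak_id"])


def make_pet(c1, s1, e1, st1, c2, s2, e2, st2, name="x"):
    return dict(chrom1=c1, start1=s1, end1=e1, strand1=st1,
                chrom2=c2, start2=s2, end2=e2, strand2=st2, name=name)


def pet_frame(*pets):
    return pd.DataFrame(list(pets))


@pytest.fixture
def five_null_peaks():
    """Five well-separated peaks with graded intensities on one chromosome."""
    return make_peaks([1_000_000 * (i + 1) for i in range(5)],
                      [1, 2, 3, 4, 5])


@pytest.fixture
def toy_genome():
    genes = pd.DataFrame(
        [("G00000", "chr1", "+", 100_000, 130_000, True, True, 0),
         ("G00001", "chr1", "-", 260_000, 240_000, True, False, 0),
         ("G00002", "chr1", "+", 500_000, 520_000, False, False, -1)],
        columns=["gene_id", "chrom", "strand", "tss", "tes",
                 "housekeeping", "metabolic", "cluster_id"])
    return GenomeModel([("chr1", 1_000_000)], genes)


def planted_scenario(seed, n_peaks=200, n_planted=10, extra=20,
                     n_background=10_000, chrom="chr1"):
    """Planted-loop study condition: loops hidden in intensity-proportional
    background over well-separated peaks. Returns (pets, peaks, truth set)."""
    from roninloops.synthetic import simulate_pets

    rng = np.random.default_rng(seed)
    peaks = make_peaks([50_000 + 100_000 * i for i in range(n_peaks)],
                       rng.uniform(1, 5, size=n_peaks), chrom=chrom)
    ids = peaks["peak_id"].to_numpy()
    pairs = set()
    while len(pairs) < n_planted:
        i, j = sorted(rng.choice(n_peaks, 2, replace=False))
        if j - i > 1:
            pairs.add((int(i), int(j)))
    planted = tuple((ids[i], ids[j], extra) for i, j in sorted(pairs))
    cfg = SyntheticConfig(n_background_pets=n_background,
                          planted_loops=planted,
                          self_ligation_fraction=0.0, inter_fraction=0.0,
                          duplicate_rate=0.0, seed=seed)
    pets, _ = simulate_pets(peaks, cfg)
    truth = {(ids[i], ids[j]) for i, j in pairs}
    return pets, peaks, truth
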