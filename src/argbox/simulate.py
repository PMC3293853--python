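"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the pipeline end to end without any external data:

* :func:`gen_expression` — an M_g matrix for the 4-condition x 4-replicate
  reference design (7728-gene scale by default is not required; sizes are
  parameters), with planted condition-mean patterns drawn from the 13
  profile subtypes plus Gaussian replicate noise on the log2 scale;
* :func:`gen_sites` — aligned operator sites as a consensus with i.i.d.
  per-position substitutions;
* :func:`gen_genome` — an i.i.d. background genome of given GC content
  with non-overlapping planted sites and an exact truth table.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contrasts import CONDITIONS, ExpressionSet
from .model import BASES, SiteSet, reverse_complement

__all__ = [
    "SUBTYPE_MEAN_PATTERNS", "DEFAULT_CONSENSUS",
    "gen_expression", "gen_sites", "gen_genome", "gen_spot_table",
]

#: Condition-mean multipliers (A, B, C, D) per profile subtype, in units of
#: half the effect size.  Multiplying by effect/... see gen_expression.
#: Chosen so the noise-free contrast signs reproduce each subtype's H_r
#: pattern under the default rule table.
SUBTYPE_MEAN_PATTERNS: dict[str, tuple[float, float, float, float]] = {
    "I.1": (0, 0, 1, 1),
    "I.2": (0, -1, 1, 0),
    "I.3": (0, 0, 1, 2),
    "I.4": (0, -1, 1, 1),
    "I.5": (0, -1, 1, 2),
    "II.1": (1, 1, 0, 0),
    "II.2": (1, 2, 0, 1),
    "II.3": (1, 1, 0, -1),
    "II.4": (1, 2, 0, 0),
    "II.5": (1, 2, 0, -1),
    "III": (0, 1, 0, -1),
    "IV": (0, 1, 0, 1),
    "V": (0, -1, 0, 1),
}

#: Synthetic stand-in for an ARG-box consensus: a perfect 20-nt palindrome
#: (the real operator is an imperfect palindrome of the same width).
DEFAULT_CONSENSUS = "TGAATCGCATATGCGATTCA"


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_expression(
    n_genes: int = 5000,
    *,
    profile_mix: dict[str, int] | None = None,
    effect: float = 2.0,
    noise_sd: float = 0.3,
    n_reps: int = 4,
    seed: int | None = None,
) -> tuple[ExpressionSet, pd.DataFrame]:
    """Simulate a normalized M_g matrix plus its ground truth.

    ``profile_mix`` maps subtype labels to planted gene counts (default:
    20 genes per each of the 13 subtypes); remaining genes are nulls with
    identical condition means.  Planted condition means are the subtype's
    pattern scaled by ``effect`` (so the largest single-contrast change is
    ``2*effect`` for the steepest subtypes); replicate noise is
    N(0, noise_sd^2) i.i.d. on the log2 scale.

    Returns the :class:`~argbox.contrasts.ExpressionSet` and a truth table
    with each gene's subtype ("null" for unplanted) and mean 4-tuple.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if effect < 0 or noise_sd < 0:
        raise ValueError("effect and noise_sd must be >= 0")
    if profile_mix is None:
        profile_mix = {name: 20 for name in SUBTYPE_MEAN_PATTERNS}
    unknown = set(profile_mix) - set(SUBTYPE_MEAN_PATTERNS)
    if unknown:
        raise ValueError(f"unknown subtypes: {sorted(unknown)}")
    n_planted = sum(profile_mix.values())
    if n_planted > n_genes:
        raise ValueError(
            f"{n_planted} planted profiles requested for {n_genes} genes")

    rng = _rng(seed)
    labels = []
    means = np.zeros((n_genes, 4))
    row = 0
    for name, count in profile_mix.items():
        pattern = np.asarray(SUBTYPE_MEAN_PATTERNS[name], float)
        for _ in range(count):
            means[row] = pattern * effect
            labels.append(name)
            row += 1
    labels.extend(["null"] * (n_genes - row))

    arrays = [f"{c}_{r + 1}" for c in CONDITIONS for r in range(n_reps)]
    cond_of_array = np.repeat(np.arange(4), n_reps)
    data = means[:, cond_of_array] + rng.normal(
        0.0, noise_sd, size=(n_genes, len(arrays)))

    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    mg = pd.DataFrame(data, index=genes, columns=arrays)
    conditions = pd.Series([a.split("_")[0] for a in arrays], index=arrays,
                           name="condition")
    replicates = pd.Series([int(a.split("_")[1]) for a in arrays],
                           index=arrays, name="replicate")
    truth = pd.DataFrame(
        {"subtype": labels,
         "mean_A": means[:, 0], "mean_B": means[:, 1],
         "mean_C": means[:, 2], "mean_D": means[:, 3]},
        index=genes)
    return ExpressionSet(mg=mg, conditions=conditions,
                         replicates=replicates), truth


def gen_sites(
    consensus: str = DEFAULT_CONSENSUS,
    n_sites: int = 22,
    mutation_rate: float = 0.05,
    seed: int | None = None,
) -> SiteSet:
    """Sample aligned sites from a consensus with i.i.d. substitutions.

    Each position mutates with probability ``mutation_rate`` to one of the
    three alternative bases, chosen uniformly.
    """
    if not 0 <= mutation_rate <= 0.75:
        raise ValueError("mutation_rate must be in [0, 0.75]")
    rng = _rng(seed)
    consensus = consensus.upper()
    L = len(consensus)
    sites = []
    for i in range(n_sites):
        chars = list(consensus)
        mutate = rng.random(L) < mutation_rate
        for l in np.flatnonzero(mutate):
            alternatives = [b for b in BASES if b != chars[l]]
            chars[l] = alternatives[rng.integers(3)]
        sites.append("".join(chars))
    return SiteSet(sites, ids=tuple(f"site{i + 1}" for i in range(n_sites)))


def gen_genome(
    length: int = 100_000,
    gc: float = 0.72,
    *,
    sites: SiteSet | None = None,
    n_plant: int = 0,
    positions: list[int] | None = None,
    strands: list[str] | None = None,
    chrom: str = "chr",
    seed: int | None = None,
) -> tuple[str, pd.DataFrame]:
    """An i.i.d. background genome with planted sites and its truth table.

    Background bases are drawn with the requested GC fraction split evenly
    between G and C (and AT likewise).  ``n_plant`` sites are drawn (with
    replacement) from ``sites`` and written over the background at
    non-overlapping positions, random strands; explicit ``positions`` /
    ``strands`` may be given instead.  The truth table is BED-like
    (0-based half-open) and records the exact planted sequence as it reads
    on its strand.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = _rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    base_idx = rng.choice(4, size=length, p=probs)
    genome = np.frombuffer("ACGT".encode(), dtype=np.uint8)[base_idx].copy()

    records = []
    if sites is not None and (n_plant > 0 or positions is not None):
        L = sites.width
        if positions is None:
            positions = _sample_nonoverlapping(rng, length, L, n_plant)
        else:
            check = sorted(positions)
            for a, b in zip(check, check[1:]):
                if b < a + L:
                    raise ValueError(f"planted sites at {a} and {b} overlap")
            if check and (check[0] < 0 or check[-1] + L > length):
                raise ValueError("planted site outside genome bounds")
        if strands is None:
            strands = ["+" if rng.random() < 0.5 else "-" for _ in positions]
        for i, (pos, strand) in enumerate(zip(positions, strands)):
            site_seq = sites.sites[int(rng.integers(len(sites)))]
            emit = site_seq if strand == "+" else reverse_complement(site_seq)
            genome[pos:pos + L] = np.frombuffer(emit.encode(), dtype=np.uint8)
            records.append((chrom, pos, pos + L, f"planted{i + 1}", site_seq,
                            strand))
    truth = pd.DataFrame(
        records, columns=["chrom", "start", "end", "name", "site_seq",
                          "strand"])
    return genome.tobytes().decode(), truth


def _sample_nonoverlapping(rng, length: int, width: int, n: int,
                           max_tries: int = 10_000) -> list[int]:
    taken: list[int] = []
    for _ in range(max_tries):
        if len(taken) == n:
            break
        pos = int(rng.integers(0, length - width + 1))
        if all(abs(pos - t) >= width for t in taken):
            taken.append(pos)
    if len(taken) < n:
        raise ValueError(
            f"could not place {n} non-overlapping sites of width {width} "
            f"in {length} nt")
    return sorted(taken)


def gen_spot_table(
    n_genes: int = 1000,
    *,
    n_tips: int = 8,
    tip_offsets: np.ndarray | None = None,
    trend: float = 0.0,
    noise_sd: float = 0.1,
    mask_fraction: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Raw two-channel spot intensities for normalization testing.

    Each gene gets duplicate spots.  The latent M of each spot is tip
    offset + ``trend``-scaled intensity bias + noise; intensities are
    reconstructed as Cy3 = 2^(A + M/2), Cy5 = 2^(A - M/2) with A uniform
    on [8, 14].  ``mask_fraction`` of spots are flagged.
    """
    rng = _rng(seed)
    n_spots = 2 * n_genes
    if tip_offsets is None:
        tip_offsets = np.zeros(n_tips)
    tips = np.repeat(np.arange(n_tips), int(np.ceil(n_spots / n_tips)))[:n_spots]
    a = rng.uniform(8, 14, n_spots)
    m = (np.asarray(tip_offsets)[tips]
         + trend * (a - a.mean())
         + rng.normal(0, noise_sd, n_spots))
    return pd.DataFrame({
        "spot_id": [f"s{i + 1}" for i in range(n_spots)],
        "gene_id": [f"g{i // 2 + 1:05d}" for i in range(n_spots)],
        "tip": tips,
        "cy3": np.exp2(a + m / 2),
        "cy5": np.exp2(a - m / 2),
        "mask": (rng.random(n_spots) < mask_fraction).astype(int),
    })
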