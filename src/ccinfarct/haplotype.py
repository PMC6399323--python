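"""Founder-of-origin inference along inbred strain genomes.

Each Collaborative Cross strain is a homozygous mosaic of the eight founder
haplotypes, so the hidden state at every SNP is one of 8 founders. A hidden
Markov model with distance-dependent transitions is run per chromosome over
the informative SNPs (those homozygous in every founder with both alleles
represented across founders):

* emission: P(call | founder) = 1 - eps on an allele match, eps on a
  mismatch, constant for a missing call;
* transition across a gap of d bp: stay with probability exp(-gamma*d), the
  leave mass split equally among the 7 other founders;
* prior: uniform over founders.

Posterior founder probabilities come from the forward-backward algorithm
(scaled arithmetic) and double as haplotype dosages for mapping; the
maximum-a-posteriori state path (Viterbi) is also reported, segmentable into
BED-like founder intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .simulate import FounderPanel, MosaicGenome

__all__ = [
    "HMMParams",
    "HaplotypeProbs",
    "select_informative_snps",
    "infer_haplotypes",
    "infer_cohort",
    "stack_dosages",
    "DosageSet",
    "map_path_intervals",
]


@dataclass
class HMMParams:
    """Emission error, per-bp founder switch rate, and founder prior."""

    emission_error: float = 0.002
    transition_rate: float = 1e-7
    prior: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0 < self.emission_error < 0.5):
            raise ValueError("emission_error must be in (0, 0.5)")
        if self.transition_rate <= 0:
            raise ValueError("transition_rate must be > 0")
        if self.prior is not None:
            p = np.asarray(self.prior, dtype=float)
            if p.shape != (8,) or not np.isclose(p.sum(), 1):
                raise ValueError("prior must be 8 probabilities summing to 1")
            self.prior = p


@dataclass
class HaplotypeProbs:
    """Posterior founder probabilities and MAP path per chromosome for one strain."""

    strain_id: str
    chrom_names: list[str]
    positions: dict[str, np.ndarray]          # informative-SNP positions used
    posterior: dict[str, np.ndarray]          # (n_snps, 8), rows sum to 1
    map_path: dict[str, np.ndarray]           # (n_snps,) founder indices

    def dosages(self, chrom: str) -> np.ndarray:
        """Expected founder contribution per SNP (the posterior itself)."""
        return self.posterior[chrom]


def select_informative_snps(panel: FounderPanel) -> dict[str, np.ndarray]:
    """Boolean mask per chromosome of SNPs usable for founder inference.

    A SNP is informative when every founder has a non-missing call and both
    alleles appear among the founders (at least one 0 and one 1).
    """
    masks = {}
    for chrom in panel.chrom_names:
        a = panel.founder_alleles[chrom]
        total = a.sum(axis=1)
        masks[chrom] = (a >= 0).all(axis=1) & (total > 0) & (total < 8)
    return masks


def _emissions(calls: np.ndarray, alleles: np.ndarray, eps: float) -> np.ndarray:
    """(n_snps, 8) emission likelihoods; missing calls are uninformative."""
    match = calls[:, None] == alleles
    em = np.where(match, 1.0 - eps, eps)
    em[calls < 0] = 1.0
    return em


def _stay_probs(positions: np.ndarray, gamma: float) -> np.ndarray:
    return np.exp(-gamma * np.diff(positions.astype(float)))


def _forward_backward(em: np.ndarray, stay: np.ndarray, prior: np.ndarray):
    """Scaled forward-backward over the 8-founder chain.

    The transition kernel only needs the stay probability: with state vector
    f summing to s, the predicted vector is
    ``(1-p)/7 * s + (p - (1-p)/7) * f`` for stay probability p.
    """
    n, k = em.shape
    alpha = np.empty((n, k))
    scale = np.empty(n)
    a = prior * em[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for i in range(1, n):
        p = stay[i - 1]
        off = (1.0 - p) / 7.0
        pred = off + (p - off) * alpha[i - 1]
        a = pred * em[i]
        scale[i] = a.sum()
        alpha[i] = a / scale[i]
    beta = np.empty((n, k))
    beta[-1] = 1.0
    for i in range(n - 2, -1, -1):
        p = stay[i]
        off = (1.0 - p) / 7.0
        b = em[i + 1] * beta[i + 1]
        beta[i] = (off * b.sum() + (p - off) * b) / scale[i + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post


def _viterbi(em: np.ndarray, stay: np.ndarray, prior: np.ndarray) -> np.ndarray:
    n, k = em.shape
    log_em = np.log(em)
    delta = np.log(prior) + log_em[0]
    back = np.empty((n, k), dtype=np.int8)
    for i in range(1, n):
        p = stay[i - 1]
        off = (1.0 - p) / 7.0
        log_stay, log_off = np.log(p), np.log(off) if off > 0 else -np.inf
        # score[j->k]: delta[j] + log trans
        cand = delta[:, None] + np.where(np.eye(k, dtype=bool), log_stay, log_off)
        back[i] = np.argmax(cand, axis=0)
        delta = cand[back[i], np.arange(k)] + log_em[i]
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def infer_haplotypes(
    genome_or_calls,
    panel: FounderPanel,
    params: HMMParams | None = None,
    masks: dict[str, np.ndarray] | None = None,
    strain_id: str | None = None,
) -> HaplotypeProbs:
    """Forward-backward founder posteriors and Viterbi path for one strain.

    Accepts a :class:`~ccinfarct.simulate.MosaicGenome` or a dict
    ``chrom -> calls`` (0/1, -1 missing, full panel length). Only informative
    SNPs enter the chain; a chromosome with none gets a uniform posterior.
    """
    params = params or HMMParams()
    if isinstance(genome_or_calls, MosaicGenome):
        calls_by_chrom = genome_or_calls.genotypes
        strain_id = strain_id or genome_or_calls.strain_id
    else:
        calls_by_chrom = genome_or_calls
        strain_id = strain_id or "strain"
    masks = masks or select_informative_snps(panel)
    prior = params.prior if params.prior is not None else np.full(8, 1 / 8)

    positions, posterior, map_path = {}, {}, {}
    for chrom in panel.chrom_names:
        mask = masks[chrom]
        pos = panel.snp_positions[chrom][mask]
        if pos.size == 0:
            warnings.warn(f"{chrom}: no informative SNPs, uniform posterior",
                          stacklevel=2)
            positions[chrom] = pos
            posterior[chrom] = np.zeros((0, 8))
            map_path[chrom] = np.zeros(0, dtype=np.int64)
            continue
        calls = np.asarray(calls_by_chrom[chrom])[mask]
        em = _emissions(calls, panel.founder_alleles[chrom][mask], params.emission_error)
        stay = _stay_probs(pos, params.transition_rate)
        positions[chrom] = pos
        posterior[chrom] = _forward_backward(em, stay, prior)
        map_path[chrom] = _viterbi(em, stay, prior)
    return HaplotypeProbs(strain_id, panel.chrom_names, positions, posterior, map_path)


def infer_cohort(
    genomes: list[MosaicGenome],
    panel: FounderPanel,
    params: HMMParams | None = None,
) -> list[HaplotypeProbs]:
    """Run haplotype inference for every strain with a shared informative mask."""
    masks = select_informative_snps(panel)
    return [infer_haplotypes(g, panel, params, masks) for g in genomes]


@dataclass
class DosageSet:
    """Founder dosages stacked across strains for mapping: (loci, strains, 8)."""

    chrom: np.ndarray
    pos: np.ndarray
    dosages: np.ndarray
    strain_ids: list[str]

    @property
    def n_loci(self) -> int:
        return self.pos.size

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    def chromosome_mask(self, chrom: str) -> np.ndarray:
        return self.chrom == chrom


def stack_dosages(probs: list[HaplotypeProbs]) -> DosageSet:
    """Stack per-strain posteriors into a (loci, strains, 8) dosage array."""
    if not probs:
        raise ValueError("empty posterior set")
    chroms, pos_all, blocks = [], [], []
    for chrom in probs[0].chrom_names:
        pos = probs[0].positions[chrom]
        chroms.append(np.full(pos.size, chrom, dtype=object))
        pos_all.append(pos)
        blocks.append(np.stack([p.posterior[chrom] for p in probs], axis=1))
    return DosageSet(
        chrom=np.concatenate(chroms),
        pos=np.concatenate(pos_all),
        dosages=np.concatenate(blocks, axis=0),
        strain_ids=[p.strain_id for p in probs],
    )


def map_path_intervals(probs: HaplotypeProbs) -> list[tuple[str, int, int, int]]:
    """Collapse the MAP path into BED-like (chrom, start, end, founder) runs.

    Interval bounds are the positions of the first/last SNP assigned to the
    founder run (half-open on the last SNP + 1).
    """
    out = []
    for chrom in probs.chrom_names:
        path = probs.map_path[chrom]
        pos = probs.positions[chrom]
        if path.size == 0:
            continue
        start = 0
        for i in range(1, path.size + 1):
            if i == path.size or path[i] != path[start]:
                out.append(
                    (chrom, int(pos[start]), int(pos[i - 1]) + 1, int(path[start]))
                )
                start = i
    return out
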