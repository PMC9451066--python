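"""Synthetic admixed genotype panels with known ancestry truth.

The generator follows the classical admixture model: individual i draws
its ancestry fractions q_i. from a symmetric Dirichlet, population k has
allele frequency f_kj at SNP j, and the alternate-allele count is
binomial, n_ij ~ Bin(2, p_ij) with p_ij = sum_k q_ik f_kj.  Dosages are
n_ij / 2.  Per-population frequencies are drawn independently per SNP,
uniform in [0.5 - spread, 0.5 + spread]; with the default spread 0.4
frequencies span [0.1, 0.9], i.e. the common-variant regime left after
the usual MAF >= 0.1 filter.  No linkage, drift hierarchy, or phasing is
modeled — truth matrices are exact, which is the point of the fixture.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from archepop.genotype_io import GenotypeMatrix

__all__ = ["AdmixtureTruth", "simulate_panel", "add_vertex_individuals", "write_fixture_vcf"]


@dataclass
class AdmixtureTruth:
    """Ground truth of a simulated panel.

    Q : N x K row-stochastic ancestry fractions (q_ik)
    F : K x M per-population alternate-allele frequencies (f_kj)
    P : N x M binomial success probabilities, P = Q @ F
    """

    Q: np.ndarray
    F: np.ndarray
    P: np.ndarray
    seed: int

    @property
    def K(self) -> int:
        return self.Q.shape[1]


def simulate_panel(
    n: int,
    m: int,
    k: int,
    dirichlet_conc: float = 0.3,
    freq_spread: float = 0.4,
    seed: int = 0,
    Q: np.ndarray | None = None,
    F: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, AdmixtureTruth]:
    """Simulate an admixed diploid panel of n individuals x m SNPs from k populations.

    ``dirichlet_conc`` is the symmetric Dirichlet concentration of the
    ancestry rows; the default 0.3 yields realistic mixtures with some
    near-pure individuals.  ``freq_spread`` sets the half-width of the
    uniform band around 0.5 from which population allele frequencies are
    drawn.  Explicit ``Q``/``F`` override the random draws (handy for
    degenerate fixtures).  Each sample's population label is its
    majority-ancestry component.
    """
    if not (n >= k >= 1 and m >= 1):
        raise ValueError(f"need n >= k >= 1 and m >= 1, got n={n}, m={m}, k={k}")
    if dirichlet_conc <= 0:
        raise ValueError("dirichlet_conc must be > 0")
    if not 0 < freq_spread <= 0.5:
        raise ValueError("freq_spread must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    if F is None:
        F = rng.uniform(0.5 - freq_spread, 0.5 + freq_spread, size=(k, m))
    else:
        F = np.asarray(F, dtype=float)
        if F.shape != (k, m) or F.min() < 0 or F.max() > 1:
            raise ValueError("F must be k x m with entries in [0, 1]")
    if Q is None:
        Q = rng.dirichlet(np.full(k, dirichlet_conc), size=n)
    else:
        Q = np.asarray(Q, dtype=float)
        if Q.shape != (n, k) or np.abs(Q.sum(axis=1) - 1).max() > 1e-8 or Q.min() < 0:
            raise ValueError("Q must be n x k row-stochastic")
    P = Q @ F
    counts = rng.binomial(2, P)
    panel = GenotypeMatrix(
        dosages=counts / 2.0,
        sample_ids=[f"sim{i:04d}" for i in range(n)],
        variant_ids=[f"snp{j:05d}" for j in range(m)],
        populations=[f"pop{int(np.argmax(Q[i]))}" for i in range(n)],
    )
    return panel, AdmixtureTruth(Q=Q, F=F, P=P, seed=seed)


def add_vertex_individuals(
    panel: GenotypeMatrix, truth: AdmixtureTruth, per_pop: int = 1, seed: int = 0
) -> tuple[GenotypeMatrix, AdmixtureTruth]:
    """Append ``per_pop`` pure-ancestry individuals for every population.

    Each appended individual has a one-hot ancestry row and genotypes
    drawn Bin(2, f_kj)/2 from its population's frequencies, placing real
    samples at (or near) the vertices of the ancestry simplex so the
    convex-hull-constrained archetypes have attainable extremes.
    """
    if per_pop < 1:
        raise ValueError("per_pop must be >= 1")
    rng = np.random.default_rng(seed)
    k, m = truth.F.shape
    rows, q_rows, ids, pops = [], [], [], []
    for pop in range(k):
        for r in range(per_pop):
            rows.append(rng.binomial(2, truth.F[pop]) / 2.0)
            q = np.zeros(k)
            q[pop] = 1.0
            q_rows.append(q)
            ids.append(f"vertex_p{pop}_{r}")
            pops.append(f"pop{pop}")
    dosages = np.vstack([panel.dosages, np.array(rows)])
    Q = np.vstack([truth.Q, np.array(q_rows)])
    new_panel = GenotypeMatrix(
        dosages=dosages,
        sample_ids=list(panel.sample_ids) + ids,
        variant_ids=list(panel.variant_ids),
        populations=(list(panel.populations) if panel.populations is not None else ["?"] * panel.n_samples) + pops,
    )
    return new_panel, AdmixtureTruth(Q=Q, F=truth.F, P=Q @ truth.F, seed=truth.seed)


def write_fixture_vcf(panel: GenotypeMatrix, path: str | os.PathLike, seed: int = 0) -> None:
    """Write a panel of hard genotype calls as a minimal VCF 4.2 file.

    Dosages must be exact diploid calls in {0, 0.5, 1} (0 -> 0/0,
    0.5 -> 0/1, 1 -> 1/1); an imputed fractional dosage cannot be
    expressed as a GT field and raises.  Missing-masked entries become
    './.'.  REF/ALT bases are drawn from ``seed`` and carry no meaning.
    """
    gt_map = {0.0: "0/0", 0.5: "0/1", 1.0: "1/1"}
    d = panel.dosages
    ok = np.isin(d, [0.0, 0.5, 1.0]) | panel.missing_mask
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValueError(f"dosage {d[i, j]} at sample {i}, variant {j} is not a diploid call in {{0, 0.5, 1}}")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=1,length={10 * (panel.n_variants + 1)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.sample_ids) + "\n")
        for j in range(panel.n_variants):
            ref, alt = rng.choice(4, size=2, replace=False)
            gts = [
                "./." if panel.missing_mask[i, j] else gt_map[d[i, j]]
                for i in range(panel.n_samples)
            ]
            fh.write(
                f"1\t{10 * (j + 1)}\t{panel.variant_ids[j]}\t{bases[ref]}\t{bases[alt]}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
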