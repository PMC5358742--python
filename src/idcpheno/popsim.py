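"""Simulated inbred genotype panels and replicated quantitative traits.

Panels emulate a germplasm collection of fully inbred lines genotyped
on a SNP chip: biallelic dosages coded {0, 2} (no heterozygotes),
local LD from a copy-with-probability Markov chain along each
chromosome, planted QTL, a kinship-correlated polygenic background,
and a replicated trait observed in a randomized complete block design.
A SPAD-like surrogate (leaf greenness) correlated with the genetic
value can be attached for fixed-covariate prediction models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "TraitArchitecture",
    "simulate_genotypes",
    "simulate_phenotypes",
    "effect_for_target_r2",
]


@dataclass
class GenotypeMatrix:
    """Inbred dosage matrix with a genetic map.

    ``dosages`` is n_lines x m_snps float with values in {0, 2} and
    ``nan`` for missing calls.  Positions are strictly increasing
    within each chromosome.
    """

    dosages: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    snp_ids: np.ndarray
    line_ids: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.snp_ids = np.asarray(self.snp_ids)
        self.line_ids = np.asarray(self.line_ids)
        n, m = self.dosages.shape
        if not (len(self.chrom) == len(self.pos) == len(self.snp_ids) == m):
            raise ValueError("map arrays must match the number of SNPs")
        if len(self.line_ids) != n:
            raise ValueError("line_ids must match the number of lines")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if (np.diff(p) <= 0).any():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def m_snps(self) -> int:
        return self.dosages.shape[1]

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency p per SNP, ignoring missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def select(self, snp_keep=None, line_keep=None) -> "GenotypeMatrix":
        s = slice(None) if snp_keep is None else snp_keep
        l = slice(None) if line_keep is None else line_keep
        return GenotypeMatrix(
            dosages=self.dosages[l][:, s],
            chrom=self.chrom[s],
            pos=self.pos[s],
            snp_ids=self.snp_ids[s],
            line_ids=self.line_ids[l],
        )

    # ---- I/O ------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Dosage CSV: one row per SNP with map columns, lines as columns."""
        df = pd.DataFrame(self.dosages.T, columns=self.line_ids)
        df.insert(0, "pos", self.pos)
        df.insert(0, "chrom", self.chrom)
        df.insert(0, "snp", self.snp_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path)
        lines = [c for c in df.columns if c not in ("snp", "chrom", "pos")]
        return cls(
            dosages=df[lines].to_numpy(dtype=float).T,
            chrom=df["chrom"].to_numpy(),
            pos=df["pos"].to_numpy(),
            snp_ids=df["snp"].to_numpy(),
            line_ids=np.asarray(lines),
        )

    def to_vcf(self, path) -> None:
        """Minimal VCF 4.2 with homozygous GT calls (./., 0/0 or 1/1)."""
        gt_map = {0.0: "0/0", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for c in pd.unique(self.chrom):
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(map(str, self.line_ids)) + "\n")
            for j in range(self.m_snps):
                calls = [
                    "./." if np.isnan(d) else gt_map[d]
                    for d in self.dosages[:, j]
                ]
                fh.write(
                    f"{self.chrom[j]}\t{self.pos[j]}\t{self.snp_ids[j]}"
                    "\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        lines = np.asarray(vcf.samples)
        chrom, pos, ids, rows = [], [], [], []
        for var in vcf:
            chrom.append(var.CHROM)
            pos.append(var.POS)
            ids.append(var.ID or f"{var.CHROM}_{var.POS}")
            gts = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            d = np.where(gts == 0, 0.0,
                         np.where(gts == 3, 2.0,
                                  np.where(gts == 1, 1.0, np.nan)))
            rows.append(d)
        vcf.close()
        return cls(
            dosages=np.asarray(rows, dtype=float).T,
            chrom=np.asarray(chrom),
            pos=np.asarray(pos),
            snp_ids=np.asarray(ids),
            line_ids=lines,
        )


def simulate_genotypes(
    n_lines: int = 400,
    m_snps: int = 2000,
    n_chrom: int = 20,
    ld_rho: float = 0.6,
    maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Inbred panel with first-order Markov LD along each chromosome.

    Each line carries one haplotype (inbred): allele j copies allele
    j-1 with probability ``ld_rho`` and is otherwise redrawn at the
    SNP's target frequency, giving adjacent-allele correlation close to
    ``ld_rho`` when neighbouring frequencies are similar.  Dosage is
    twice the allele.  Missing calls are inserted completely at random.
    """
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError("ld_rho must lie in [0, 1)")
    lo, hi = maf_range
    if not (0.0 <= lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 <= lo <= hi <= 0.5")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    per_chrom = np.full(n_chrom, m_snps // n_chrom)
    per_chrom[: m_snps % n_chrom] += 1
    freqs = rng.uniform(lo, hi, m_snps)  # target alt frequency == MAF side
    alleles = np.empty((n_lines, m_snps), dtype=np.int8)
    chrom = np.empty(m_snps, dtype=object)
    pos = np.empty(m_snps, dtype=np.int64)
    j0 = 0
    for c, mc in enumerate(per_chrom, start=1):
        a_prev = None
        for j in range(j0, j0 + mc):
            fresh = (rng.random(n_lines) < freqs[j]).astype(np.int8)
            if a_prev is None:
                a = fresh
            else:
                copy = rng.random(n_lines) < ld_rho
                a = np.where(copy, a_prev, fresh)
            alleles[:, j] = a
            a_prev = a
        chrom[j0 : j0 + mc] = f"Gm{c:02d}"
        pos[j0 : j0 + mc] = 10_000 * (1 + np.arange(mc))
        j0 += mc
    dos = alleles.astype(float) * 2.0
    if missing_rate > 0:
        dos[rng.random(dos.shape) < missing_rate] = np.nan
    return GenotypeMatrix(
        dosages=dos,
        chrom=chrom.astype(str),
        pos=pos,
        snp_ids=np.array([f"snp{j:05d}" for j in range(m_snps)]),
        line_ids=np.array([f"PI{i:04d}" for i in range(n_lines)]),
    )


@dataclass
class TraitArchitecture:
    """Genetic architecture of the simulated trait.

    ``qtl`` is a sequence of ``(snp_index, additive_effect)`` pairs
    (effect per dosage unit).  ``h2`` is the target heritability on a
    line-mean basis: Var(g) / (Var(g) + sigma_e^2 / n_reps).  The total
    genetic value (QTL + polygenic) is rescaled so the realised
    line-mean h2 matches ``h2`` exactly against ``residual_var``.
    ``spad_corr``, if not None, attaches a surrogate greenness column
    with corr(spad, genetic value) = -spad_corr (greener = healthier).
    """

    qtl: tuple = ()
    polygenic_var: float = 1.0
    h2: float = 0.6
    n_reps: int = 4
    rep_var: float = 0.1
    residual_var: float = 1.0
    spad_corr: float | None = 0.6

    def __post_init__(self):
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if min(self.polygenic_var, self.rep_var, self.residual_var) < 0:
            raise ValueError("variances must be non-negative")


def _imputed_dosages(g: GenotypeMatrix) -> np.ndarray:
    d = g.dosages.copy()
    if np.isnan(d).any():
        means = np.nanmean(d, axis=0)
        idx = np.where(np.isnan(d))
        d[idx] = means[idx[1]]
    return d


def simulate_phenotypes(
    g: GenotypeMatrix, arch: TraitArchitecture, seed: int = 0
) -> pd.DataFrame:
    """Replicated trait observations for a panel.

    Returns a tidy table with columns ``line``, ``rep``, ``value`` and,
    when ``arch.spad_corr`` is set, a per-line ``spad`` column.  The
    observation model is value = mu + g_line + rep_effect + residual
    with the genetic values rescaled so the line-mean heritability
    equals ``arch.h2``.
    """
    rng = np.random.default_rng(seed)
    d = _imputed_dosages(g)
    n, m = d.shape
    for j, _ in arch.qtl:
        if not 0 <= int(j) < m:
            raise ValueError(f"QTL index {j} out of range for {m} SNPs")
    gval = np.zeros(n)
    for j, eff in arch.qtl:
        gval += float(eff) * d[:, int(j)]
    if arch.polygenic_var > 0:
        W = d - d.mean(axis=0)
        u = W @ rng.normal(size=m)
        sd = u.std()
        if sd > 0:
            u *= np.sqrt(arch.polygenic_var) / sd
        gval = gval + u
    gval = gval - gval.mean()
    sigma_e2 = arch.residual_var
    if arch.h2 == 0.0:
        gval = np.zeros(n)
    else:
        vg = gval.var()
        if vg <= 0:
            raise ValueError(
                "target h2 > 0 unreachable: simulated genetic variance is zero "
                "(no QTL and polygenic_var = 0)"
            )
        if arch.h2 == 1.0:
            sigma_e2 = 0.0
        else:
            target_vg = arch.h2 / (1.0 - arch.h2) * sigma_e2 / arch.n_reps
            gval *= np.sqrt(target_vg / vg)
    mu = 3.0  # ordinal-scale-like grand mean; location does not matter downstream
    rep_eff = rng.normal(0.0, np.sqrt(arch.rep_var), arch.n_reps)
    rows = []
    for r in range(arch.n_reps):
        resid = rng.normal(0.0, np.sqrt(sigma_e2), n)
        rows.append(
            pd.DataFrame(
                {
                    "line": g.line_ids,
                    "rep": f"rep{r + 1}",
                    "value": mu + gval + rep_eff[r] + resid,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    if arch.spad_corr is not None:
        r = float(arch.spad_corr)
        if not 0.0 <= r <= 1.0:
            raise ValueError("spad_corr must lie in [0, 1]")
        gsd = gval.std()
        z = gval / gsd if gsd > 0 else np.zeros(n)
        noise = rng.normal(size=n)
        noise = (noise - noise.mean()) / noise.std()
        spad_z = -r * z + np.sqrt(max(1.0 - r**2, 0.0)) * noise
        spad = 40.0 + 5.0 * spad_z
        out = out.merge(
            pd.DataFrame({"line": g.line_ids, "spad": spad}), on="line", how="left"
        )
    return out


def effect_for_target_r2(
    g: GenotypeMatrix, snp_index: int, target_r2: float, arch: TraitArchitecture
) -> float:
    """Additive effect making one QTL explain ``target_r2`` of line-mean
    phenotypic variance under ``arch`` (given its h2 and polygenic_var).

    The QTL's share of genetic variance must be f = target_r2 / h2 < 1;
    the effect solves a^2 * Var(dosage) = polygenic_var * f / (1 - f).
    """
    if arch.h2 <= 0:
        raise ValueError("target R2 requires h2 > 0")
    f = target_r2 / arch.h2
    if not 0.0 < f < 1.0:
        raise ValueError("target_r2 must be positive and below h2")
    v = _imputed_dosages(g)[:, int(snp_index)].var()
    if v <= 0:
        raise ValueError("QTL SNP is monomorphic")
    return float(np.sqrt(arch.polygenic_var * f / (1.0 - f) / v))
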