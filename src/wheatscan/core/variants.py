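"""Biallelic SNP tables with per-sample genotype, depth and allele depths.

Genotype coding (inbred, haploid-coded): 0 = hom ref, 1 = hom alt,
2 = heterozygous, -1 = missing. Positions are 1-based (VCF convention).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

GT_REF = 0
GT_ALT = 1
GT_HET = 2
GT_MISSING = -1

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">
"""

_GT_STR = {GT_REF: "0/0", GT_ALT: "1/1", GT_HET: "0/1", GT_MISSING: "./."}


class VariantTable:
    """Biallelic SNP records plus per-sample genotype/depth matrices.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom``, ``pos`` (1-based int), ``ref``,
        ``alt`` and optionally extra annotation columns (QUAL, FS, MQ, ...).
    gt, dp, ad_ref, ad_alt
        Arrays of shape (n_sites, n_samples). ``dp``/``ad_*`` may be None.
    samples
        Sample identifiers, one per matrix column.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        gt: np.ndarray,
        samples: list[str],
        dp: np.ndarray | None = None,
        ad_ref: np.ndarray | None = None,
        ad_alt: np.ndarray | None = None,
    ):
        n = len(sites)
        gt = np.asarray(gt, dtype=np.int8)
        if gt.shape != (n, len(samples)):
            raise ValueError(
                f"genotype matrix shape {gt.shape} does not match "
                f"{n} sites x {len(samples)} samples"
            )
        self.sites = sites.reset_index(drop=True)
        self.gt = gt
        self.samples = list(samples)
        self.dp = None if dp is None else np.asarray(dp, dtype=np.int32)
        self.ad_ref = None if ad_ref is None else np.asarray(ad_ref, dtype=np.int32)
        self.ad_alt = None if ad_alt is None else np.asarray(ad_alt, dtype=np.int32)
        self._check_sorted()

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def _check_sorted(self) -> None:
        if len(self.sites) < 2:
            return
        grp = self.sites.groupby("chrom", sort=False)["pos"]
        if not bool(grp.apply(lambda p: p.is_monotonic_increasing and p.is_unique).all()):
            raise ValueError("positions must be strictly increasing within chromosome")

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample!r}") from None

    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        mask = np.asarray(mask, dtype=bool)
        return VariantTable(
            self.sites.loc[mask],
            self.gt[mask],
            self.samples,
            dp=None if self.dp is None else self.dp[mask],
            ad_ref=None if self.ad_ref is None else self.ad_ref[mask],
            ad_alt=None if self.ad_alt is None else self.ad_alt[mask],
        )

    def subset_samples(self, samples: list[str]) -> "VariantTable":
        idx = [self.sample_index(s) for s in samples]
        return VariantTable(
            self.sites,
            self.gt[:, idx],
            list(samples),
            dp=None if self.dp is None else self.dp[:, idx],
            ad_ref=None if self.ad_ref is None else self.ad_ref[:, idx],
            ad_alt=None if self.ad_alt is None else self.ad_alt[:, idx],
        )

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def read_vcf(cls, path: str | Path) -> "VariantTable":
        """Read a VCF (plain or bgzipped); keeps only biallelic SNP records."""
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
        rows, gts, dps, adr, ada = [], [], [], [], []
        extras: dict[str, list] = {}
        extra_keys = ("FS", "MQ", "GQ", "QD")
        for var in vcf:
            if not var.is_snp or len(var.ALT) != 1:
                continue
            rows.append((var.CHROM, var.POS, var.REF, var.ALT[0], var.QUAL))
            # gts012: 0=hom ref, 1=het, 2=hom alt, 3=unknown
            g = np.asarray(var.gt_types, dtype=np.int8)
            gts.append(
                np.select(
                    [g == 0, g == 2, g == 1], [GT_REF, GT_ALT, GT_HET], GT_MISSING
                ).astype(np.int8)
            )
            fmts = var.FORMAT
            if "DP" in fmts:
                d = var.format("DP")
                dps.append(np.where(d < 0, 0, d).reshape(-1).astype(np.int32))
            if "AD" in fmts:
                ad = var.format("AD")
                ad = np.where(ad < 0, 0, ad)
                adr.append(ad[:, 0].astype(np.int32))
                ada.append(ad[:, 1].astype(np.int32) if ad.shape[1] > 1 else
                           np.zeros(len(samples), np.int32))
            for key in extra_keys:
                val = var.INFO.get(key)
                if val is not None:
                    extras.setdefault(key, [np.nan] * (len(rows) - 1)).append(val)
                elif key in extras:
                    extras[key].append(np.nan)
        sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual"])
        for key, vals in extras.items():
            sites[key] = vals
        n = len(sites)
        return cls(
            sites,
            np.array(gts, dtype=np.int8).reshape(n, len(samples)),
            samples,
            dp=np.array(dps, np.int32) if len(dps) == n else None,
            ad_ref=np.array(adr, np.int32) if len(adr) == n else None,
            ad_alt=np.array(ada, np.int32) if len(ada) == n else None,
        )

    def write_vcf(self, path: str | Path) -> None:
        """Write VCF v4.2 with GT:DP:AD (DP/AD zero-filled when absent)."""
        dp = self.dp if self.dp is not None else np.zeros_like(self.gt, np.int32)
        adr = self.ad_ref if self.ad_ref is not None else np.zeros_like(dp)
        ada = self.ad_alt if self.ad_alt is not None else np.zeros_like(dp)
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER)
            for chrom, length in self._contig_spans().items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            chroms = self.sites["chrom"].to_numpy()
            poss = self.sites["pos"].to_numpy()
            refs = self.sites["ref"].to_numpy()
            alts = self.sites["alt"].to_numpy()
            quals = (
                self.sites["qual"].to_numpy()
                if "qual" in self.sites
                else np.full(len(self), np.nan)
            )
            for i in range(len(self)):
                q = "." if pd.isna(quals[i]) else f"{quals[i]:g}"
                cells = "\t".join(
                    f"{_GT_STR[g]}:{d}:{r},{a}"
                    for g, d, r, a in zip(self.gt[i], dp[i], adr[i], ada[i])
                )
                fh.write(
                    f"{chroms[i]}\t{poss[i]}\t.\t{refs[i]}\t{alts[i]}\t{q}\t"
                    f"PASS\t.\tGT:DP:AD\t{cells}\n"
                )

    def _contig_spans(self) -> dict[str, int]:
        if len(self) == 0:
            return {}
        return self.sites.groupby("chrom", sort=False)["pos"].max().to_dict()

    def __repr__(self) -> str:
        return f"VariantTable({len(self)} sites, {self.n_samples} samples)"
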