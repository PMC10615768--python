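"""Genotype dosage panels and variant-key utilities.

Variant keys are strings of the form ``chrom:pos:ref:alt`` (1-based
position).  Dosages are alternative-allele counts in [0, 2]; fractional
values are allowed (imputed genotypes).
"""
from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_KEY_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<pos>\d+):(?P<ref>[ACGTacgt]+):(?P<alt>[ACGTacgt]+)$")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def parse_variant_key(key: str) -> tuple[str, int, str, str]:
    m = _KEY_RE.match(key)
    if m is None:
        raise ValueError(f"malformed variant key {key!r}; expected chrom:pos:ref:alt")
    return m["chrom"], int(m["pos"]), m["ref"].upper(), m["alt"].upper()


def make_variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{int(pos)}:{ref}:{alt}"


def complement_allele(allele: str) -> str:
    return allele.translate(_COMPLEMENT)[::-1].upper() if len(allele) > 1 else allele.translate(_COMPLEMENT).upper()


def is_palindromic(ref: str, alt: str) -> bool:
    """True for strand-ambiguous SNVs (A/T or C/G pairs)."""
    return {ref.upper(), alt.upper()} in ({"A", "T"}, {"C", "G"})


def variant_table(keys: Iterable[str]) -> pd.DataFrame:
    rows = [parse_variant_key(k) for k in keys]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"], index=pd.Index(keys, name="variant"))
    return df


class GenotypePanel:
    """A samples x variants dosage matrix with parsed variant metadata.

    Parameters
    ----------
    dosages:
        DataFrame indexed by sample id with variant-key columns.
    variants:
        Optional metadata table indexed by variant key.  Recognised extra
        columns: ``score`` (imputation quality in [0, 1]).  When omitted the
        table is parsed from the keys and ``score`` defaults to 1.0.
    """

    def __init__(self, dosages: pd.DataFrame, variants: pd.DataFrame | None = None):
        self.dosages = dosages
        if variants is None:
            variants = variant_table(dosages.columns)
        else:
            variants = variants.loc[dosages.columns].copy()
        if "score" not in variants.columns:
            variants["score"] = 1.0
        self.variants = variants

    # -- basic accessors ---------------------------------------------------
    @property
    def samples(self) -> pd.Index:
        return self.dosages.index

    @property
    def variant_keys(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_samples(self) -> int:
        return len(self.dosages.index)

    def maf(self) -> pd.Series:
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def variants_in_region(self, chrom: str, start: int, end: int) -> list[str]:
        """Variant keys with 1-based position inside the closed interval."""
        v = self.variants
        mask = (v["chrom"] == chrom) & (v["pos"] >= start) & (v["pos"] <= end)
        return list(v.index[mask])

    def subset(self, keys: Sequence[str]) -> "GenotypePanel":
        return GenotypePanel(self.dosages.loc[:, list(keys)], self.variants.loc[list(keys)])

    def lookup_position(self, chrom: str, pos: int) -> list[str]:
        v = self.variants
        mask = (v["chrom"] == chrom) & (v["pos"] == pos)
        return list(v.index[mask])

    # -- I/O ---------------------------------------------------------------
    def to_dosage_tsv(self, path) -> None:
        out = self.dosages.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_dosage_tsv(cls, path) -> "GenotypePanel":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(df)

    @classmethod
    def from_vcf(cls, path) -> "GenotypePanel":
        """Read dosages from a VCF (DS FORMAT field preferred, GT fallback)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        keys, columns = [], []
        for rec in vcf:
            if len(rec.ALT) != 1:
                continue  # biallelic SNVs only
            key = make_variant_key(rec.CHROM, rec.POS, rec.REF, rec.ALT[0])
            try:
                ds = np.asarray(rec.format("DS"), dtype=float).ravel()
            except Exception:
                ds = None
            if ds is None or ds.size != len(samples):
                # GT fallback: alternative-allele count, missing -> NaN
                ds = np.array([a + b if a >= 0 and b >= 0 else np.nan
                               for a, b, *_ in rec.genotypes], dtype=float)
            keys.append(key)
            columns.append(ds)
        dosages = pd.DataFrame(np.column_stack(columns) if columns else np.empty((len(samples), 0)),
                               index=pd.Index(samples, name="sample_id"), columns=keys)
        return cls(dosages)

    def to_vcf(self, path) -> None:
        """Write a minimal text VCF with a DS FORMAT field."""
        v = self.variants.sort_values(["chrom", "pos"])
        samples = list(self.samples)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternative allele dosage">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
            for key, row in v.iterrows():
                ds = self.dosages[key].to_numpy()
                fields = [str(row["chrom"]), str(int(row["pos"])), str(key), row["ref"], row["alt"],
                          ".", "PASS", ".", "DS"]
                fields += [f"{d:.3f}" for d in ds]
                fh.write("\t".join(fields) + "\n")
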