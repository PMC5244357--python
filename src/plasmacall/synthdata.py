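"""Synthetic amplicon sequencing data with the structure the caller assumes.

The generator emulates a personalised multiplex amplicon experiment on
plasma DNA. Two stages of randomness matter for detection at low allele
fractions and both are modelled explicitly:

1. **Template bottleneck** — a plasma extraction of ~10 ng contains about
   3000 haploid genome equivalents, so the number of mutant template
   molecules entering PCR for an amplicon is Binomial(G, f) where f is the
   ctDNA allele fraction. When that draw is zero the variant is physically
   absent no matter how deep the sequencing.
2. **Read sampling and sequencing error** — read pairs are drawn uniformly
   from the G templates and each sequenced base is substituted with a
   configurable per-base error rate (default 2.8e-3, the raw-read regime of
   a MiSeq amplicon run). Mate errors are independent by default; a
   correlated mode shares error events between mates to show why merged-read
   error floors in real data exceed the independent-error prediction.

Read names encode the amplicon, template index and mutant status, so every
downstream stage can be checked against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fastqio import write_fasta, write_fastq
from .panel import Amplicon, Panel, PanelError, PanelVariant, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b

#: the nine tumour:normal part ratios of the serial dilution design
DEFAULT_DILUTION_RATIOS = (10, 20, 40, 80, 160, 320, 640, 1280, 2560)


def _seq_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def _arr_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


@dataclass(frozen=True)
class ErrorModel:
    """Per-base sequencing error model.

    substitution_rate
        Probability that a sequenced base call is substituted (default
        2.8e-3, matching the raw per-base non-reference call regime).
    mate_error_mode
        ``independent`` (default) or ``correlated``. In correlated mode a
        fraction ``mate_error_correlation`` of error events is shared
        between the two mates at the same template position (weight 1
        reproduces identical errors on both mates).
    indel_rate
        Per-base probability of a spurious 1-bp indel (default 0; the
        method targets substitution noise).
    """

    substitution_rate: float = 2.8e-3
    mate_error_mode: str = "independent"
    mate_error_correlation: float = 0.0
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "mate_error_correlation", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mate_error_mode not in ("independent", "correlated"):
            raise ValueError(f"unknown mate_error_mode {self.mate_error_mode!r}")


@dataclass(frozen=True)
class SimulationParams:
    """Sampling parameters for one simulated library."""

    genome_equivalents: int = 3000
    depth_per_amplicon: int = 2000
    ctdna_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_equivalents < 1:
            raise ValueError("genome_equivalents must be >= 1")
        if self.depth_per_amplicon < 1:
            raise ValueError("depth_per_amplicon must be >= 1")
        if not 0.0 <= self.ctdna_fraction <= 1.0:
            raise ValueError("ctdna_fraction must be in [0, 1]")


@dataclass(frozen=True)
class DilutionDesign:
    """A serial tumour-into-normal dilution design.

    ``ratios`` are tumour:normal part ratios ("1:r"); under the default
    ``parts`` convention the tumour mass fraction is d = 1/(1+r), under
    ``fraction`` it is d = 1/r. The expected variant frequency at a ratio is
    the mixture d*tumour_vaf + (1-d)*normal_vaf.
    """

    ratios: tuple = DEFAULT_DILUTION_RATIOS
    ratio_convention: str = "parts"

    def __post_init__(self) -> None:
        if len(self.ratios) == 0:
            raise ValueError("dilution design needs at least one ratio")
        if any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be positive")
        if self.ratio_convention not in ("parts", "fraction"):
            raise ValueError(f"unknown ratio_convention {self.ratio_convention!r}")

    def tumour_mass_fraction(self, ratio: float) -> float:
        if self.ratio_convention == "parts":
            return 1.0 / (1.0 + ratio)
        return 1.0 / ratio

    def expected_frequency(self, tumour_vaf: float, normal_vaf: float, ratio: float) -> float:
        d = self.tumour_mass_fraction(ratio)
        return d * tumour_vaf + (1.0 - d) * normal_vaf


@dataclass
class SimulatedReadSet:
    """Paired reads plus exact ground truth for one simulated library."""

    pairs: list  # (name, r1, r2) tuples
    ground_truth: dict  # amplicon id -> tallies
    params: SimulationParams

    def write_fastq(self, prefix) -> tuple[Path, Path]:
        prefix = Path(prefix)
        r1 = prefix.parent / (prefix.name + "_R1.fastq.gz")
        r2 = prefix.parent / (prefix.name + "_R2.fastq.gz")
        write_fastq(((n, s1) for n, s1, _ in self.pairs), r1)
        write_fastq(((n, s2) for n, _, s2 in self.pairs), r2)
        return r1, r2

    def mutant_read_count(self, amplicon_id: str) -> int:
        return self.ground_truth[amplicon_id]["mutant_reads"]


def _substitute(mat: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Substitute bases in-place with probability ``rate`` per call."""
    if rate <= 0 or mat.size == 0:
        return
    mask = rng.random(mat.shape) < rate
    n = int(mask.sum())
    if n == 0:
        return
    idx = _BASE_INDEX[mat[mask]]
    shift = rng.integers(1, 4, n)
    mat[mask] = _BASES[(idx + shift) % 4]


def _revcomp_rows(mat: np.ndarray) -> np.ndarray:
    return _COMP[mat][:, ::-1]


def _pairs_from_product(
    product: np.ndarray,
    n: int,
    read_length: int,
    error_model: ErrorModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate n read pairs from one template haplotype.

    Returns (r1, r2) uint8 matrices; r2 is already reverse-complemented to
    sequencing orientation. Error draws happen in product coordinates so the
    correlated mode can share events between mates.
    """
    p_len = len(product)
    l1 = min(read_length, p_len)
    l2 = min(read_length, p_len)
    seg1 = np.tile(product[:l1], (n, 1))
    seg2 = np.tile(product[p_len - l2 :], (n, 1))
    e = error_model.substitution_rate
    if error_model.mate_error_mode == "correlated" and e > 0:
        w = error_model.mate_error_correlation
        shared = rng.random((n, p_len)) < w * e
        k = int(shared.sum())
        if k:
            rows, cols = np.nonzero(shared)
            sub = _BASES[(_BASE_INDEX[product[cols]] + rng.integers(1, 4, k)) % 4]
            in1 = cols < l1
            seg1[rows[in1], cols[in1]] = sub[in1]
            in2 = cols >= p_len - l2
            seg2[rows[in2], cols[in2] - (p_len - l2)] = sub[in2]
        _substitute(seg1, (1.0 - w) * e, rng)
        _substitute(seg2, (1.0 - w) * e, rng)
    else:
        _substitute(seg1, e, rng)
        _substitute(seg2, e, rng)
    return seg1, _revcomp_rows(seg2)


def simulate_reads(
    panel: Panel,
    params: SimulationParams,
    error_model: ErrorModel | None = None,
    per_amplicon_fraction: Mapping[str, float] | None = None,
    read_length: int = 150,
) -> SimulatedReadSet:
    """Simulate a paired-end plasma library for a panel.

    Per amplicon: the number of mutant templates is drawn
    Binomial(genome_equivalents, fraction); each of ``depth_per_amplicon``
    read pairs picks a template uniformly and inherits its haplotype; then
    per-base errors are applied. ``per_amplicon_fraction`` overrides
    ``params.ctdna_fraction`` per amplicon id (used by the dilution series).

    Read names are ``<amplicon>|t<template>|<M|W>|<serial>`` — exact ground
    truth for assignment and counting checks.
    """
    error_model = error_model or ErrorModel()
    rng = np.random.default_rng(params.seed)
    pairs: list = []
    truth: dict = {}
    for amp in panel:
        f = params.ctdna_fraction
        if per_amplicon_fraction is not None:
            f = per_amplicon_fraction.get(amp.id, f)
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"allele fraction {f} for {amp.id} outside [0, 1]")
        g = params.genome_equivalents
        depth = params.depth_per_amplicon
        m = int(rng.binomial(g, f)) if f > 0 else 0
        template_idx = rng.integers(0, g, depth)
        is_mut = template_idx < m

        wt_product = _seq_arr(amp.product_seq)
        r1 = np.empty((depth,), dtype=object)
        r2 = np.empty((depth,), dtype=object)
        n_wt = int((~is_mut).sum())
        n_mut = int(is_mut.sum())
        w1, w2 = _pairs_from_product(wt_product, n_wt, read_length, error_model, rng)
        wt_rows = np.nonzero(~is_mut)[0]
        for j, row in enumerate(wt_rows):
            r1[row] = _arr_seq(w1[j])
            r2[row] = _arr_seq(w2[j])
        if n_mut:
            mut_product = _seq_arr(amp.alt_product_seq())
            m1, m2 = _pairs_from_product(mut_product, n_mut, read_length, error_model, rng)
            mut_rows = np.nonzero(is_mut)[0]
            for j, row in enumerate(mut_rows):
                r1[row] = _arr_seq(m1[j])
                r2[row] = _arr_seq(m2[j])
        for i in range(depth):
            tag = "M" if is_mut[i] else "W"
            name = f"{amp.id}|t{template_idx[i]}|{tag}|{i}"
            pairs.append((name, r1[i], r2[i]))
        truth[amp.id] = {
            "fraction": f,
            "genome_equivalents": g,
            "mutant_templates": m,
            "mutant_reads": n_mut,
            "depth": depth,
        }
    return SimulatedReadSet(pairs=pairs, ground_truth=truth, params=params)


def simulate_controls(
    panel: Panel,
    error_model: ErrorModel | None = None,
    n_controls: int = 3,
    seed: int = 0,
    params: SimulationParams | None = None,
) -> list[SimulatedReadSet]:
    """Simulate same-run negative-control libraries (variant-free DNA).

    Controls carry no target variants: all variant-supporting reads arise
    from the error model alone. Between 1 and 3 controls, as in a run where
    each sample is accompanied by up to three cell-line control libraries.
    """
    if not 1 <= n_controls <= 3:
        raise ValueError(f"n_controls must be in [1, 3], got {n_controls}")
    base = params or SimulationParams()
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, n_controls)
    out = []
    for s in child_seeds:
        p = SimulationParams(
            genome_equivalents=base.genome_equivalents,
            depth_per_amplicon=base.depth_per_amplicon,
            ctdna_fraction=0.0,
            seed=int(s),
        )
        out.append(simulate_reads(panel, p, error_model))
    return out


@dataclass
class DilutionSeriesResult:
    """One simulated library per dilution ratio plus the expected table."""

    read_sets: dict  # ratio -> SimulatedReadSet
    expected: pd.DataFrame  # amplicon_id, ratio, expected_frequency


def simulate_dilution_series(
    panel: Panel,
    tumour_vafs: Mapping[str, float],
    normal_vafs: Mapping[str, float],
    design: DilutionDesign | None = None,
    error_model: ErrorModel | None = None,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> DilutionSeriesResult:
    """Simulate a tumour-into-normal serial dilution series.

    For each ratio the per-amplicon allele fraction is the mixture
    expectation d*tumour_vaf + (1-d)*normal_vaf, and one full library is
    simulated at that fraction. The emitted expected-frequency table is the
    ground truth for linearity and limit-of-detection analysis.
    """
    design = design or DilutionDesign()
    base = params or SimulationParams(genome_equivalents=50000, depth_per_amplicon=5000)
    for d in (tumour_vafs, normal_vafs):
        for amp_id, v in d.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"VAF {v} for {amp_id} outside [0, 1]")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, len(design.ratios))
    read_sets = {}
    rows = []
    for ratio, s in zip(design.ratios, child_seeds):
        fractions = {}
        for amp in panel:
            tv = tumour_vafs.get(amp.id, 0.0)
            nv = normal_vafs.get(amp.id, 0.0)
            ef = design.expected_frequency(tv, nv, ratio)
            fractions[amp.id] = ef
            rows.append({"amplicon_id": amp.id, "ratio": ratio, "expected_frequency": ef})
        p = SimulationParams(
            genome_equivalents=base.genome_equivalents,
            depth_per_amplicon=base.depth_per_amplicon,
            ctdna_fraction=0.0,
            seed=int(s),
        )
        read_sets[ratio] = simulate_reads(panel, p, error_model, per_amplicon_fraction=fractions)
    return DilutionSeriesResult(read_sets=read_sets, expected=pd.DataFrame(rows))


def expected_detection_probability(f: float, g: int) -> float:
    """Probability that >=1 of ``g`` sampled templates carries the variant.

    Closed form 1 - (1-f)^g: the template-bottleneck ceiling on detection at
    allele fraction ``f`` with ``g`` genome equivalents of input, evaluated
    stably via expm1/log1p for small f.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"allele fraction must be in [0, 1], got {f}")
    if g < 1:
        raise ValueError(f"genome equivalents must be >= 1, got {g}")
    if f == 1.0:
        return 1.0
    return float(-np.expm1(g * np.log1p(-f)))


def sample_mutant_templates(f: float, g: int, n_replicates: int, seed: int = 0) -> np.ndarray:
    """Draw mutant-template counts Binomial(g, f) for replicate amplicons."""
    if not 0.0 <= f <= 1.0 or g < 1 or n_replicates < 1:
        raise ValueError("invalid template-sampling parameters")
    rng = np.random.default_rng(seed)
    return rng.binomial(g, f, n_replicates)


def template_detection_rate(f: float, g: int, n_replicates: int, seed: int = 0) -> float:
    """Monte-Carlo estimate of :func:`expected_detection_probability`.

    Fraction of replicate amplicons whose Binomial(g, f) template draw is
    nonzero — the simulated counterpart of the closed form.
    """
    counts = sample_mutant_templates(f, g, n_replicates, seed)
    return float(np.mean(counts > 0))


# ---------------------------------------------------------------------------
# panel generation


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _arr_seq(_BASES[rng.integers(0, 4, length)])


def make_panel(
    n_amplicons: int,
    insert_length_range: tuple[int, int] = (60, 150),
    seed: int = 0,
    patient_id: str = "PT01",
    primer_length: int = 20,
    indel_fraction: float = 0.0,
    origin_label: str = "primary",
) -> tuple[Panel, dict[str, str]]:
    """Generate a random panel and its reference sequences.

    Each amplicon gets unique random primers, a random insert whose length
    is drawn from ``insert_length_range`` (which must lie within [60, 150]),
    and one target variant strictly inside the insert — an SNV, or with
    probability ``indel_fraction`` a short (1-3 bp) insertion or deletion.
    Reference contigs are the full PCR products, one per amplicon. Fixed
    seed => byte-identical panel and reference.
    """
    if not 1 <= n_amplicons <= 15:
        raise PanelError(f"n_amplicons must be in [1, 15], got {n_amplicons}")
    lo, hi = insert_length_range
    if lo < 60 or hi > 150 or lo > hi:
        raise PanelError(f"insert_length_range {insert_length_range} outside [60, 150]")
    rng = np.random.default_rng(seed)
    used_primers: set[str] = set()
    amplicons = []
    refs: dict[str, str] = {}
    for i in range(n_amplicons):
        while True:
            fwd = _random_seq(rng, primer_length)
            rev = _random_seq(rng, primer_length)
            if fwd not in used_primers and rev not in used_primers and fwd != rev:
                used_primers.update((fwd, rev))
                break
        length = int(rng.integers(lo, hi + 1))
        insert = _random_seq(rng, length)
        chrom = f"{patient_id}_amp{i + 1:02d}"
        make_indel = rng.random() < indel_fraction
        if make_indel:
            off = int(rng.integers(4, length - 8))
            if rng.random() < 0.5:  # deletion of 1-3 bp, VCF anchored
                d = int(rng.integers(1, 4))
                ref_allele = insert[off : off + 1 + d]
                alt_allele = insert[off]
            else:
                ins = _random_seq(rng, int(rng.integers(1, 4)))
                ref_allele = insert[off]
                alt_allele = insert[off] + ins
        else:
            off = int(rng.integers(2, length - 2))
            ref_allele = insert[off]
            alt_idx = (int(_BASE_INDEX[ord(ref_allele)]) + int(rng.integers(1, 4))) % 4
            alt_allele = chr(_BASES[alt_idx])
        variant = PanelVariant(
            chrom=chrom,
            pos=primer_length + off + 1,
            ref=ref_allele,
            alt=alt_allele,
            gene=f"GENE{i + 1}",
            priority_class="c",
            origin_label=origin_label,
        )
        amp = Amplicon(
            id=f"AMP{i + 1:02d}",
            chrom=chrom,
            insert_start=primer_length,
            insert_end=primer_length + length,
            fwd_primer=fwd,
            rev_primer=rev,
            insert_seq=insert,
            variant=variant,
        )
        amplicons.append(amp)
        refs[chrom] = amp.product_seq
    return Panel(patient_id=patient_id, amplicons=amplicons), refs


def write_reference(refs: dict[str, str], path) -> None:
    """Write reference contigs (one per amplicon PCR product) as FASTA."""
    write_fasta(refs, path)
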