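"""Synthetic genotype generation for every pipeline stage.

The built-in panel holds the study's 32 polymorphic SNP loci (marker id,
linkage group, major/minor alleles and frequencies, per-locus call counts).
Four printed rows have frequency pairs that do not sum to one; the minor
frequency is repaired as 1 - major and the rows are flagged. One row
(31328) prints an expected heterozygosity inconsistent with its own
frequency pair; the frequencies are kept authoritative and the row is
flagged ``he_inconsistent``.

Generator modes
---------------
panmictic
    Hardy-Weinberg genotypes at the panel frequencies, identical across
    groups — the study's null. Group labels carry no signal (first 55
    benthic, next 55 littoral, last 49 pelagic by convention).
balding_nichols
    Per-group frequencies from Beta(p(1-F)/F, (1-p)(1-F)/F) at a target
    Fst, HWE within groups — planted structure with known truth.
island_forward
    Delegates to the forward island-model simulator and samples the study
    design from it.
pedigree_dyads
    Labeled dyads (unrelated, parent-offspring or full-sib) produced by
    Mendelian transmission from founders at panel frequencies — known
    relatedness truth for estimator recovery tests.
qc_fixture
    A 55-locus panel with 22 monomorphic loci and one planted strong HWE
    violation among 33 polymorphic loci, mirroring a 55 -> 33 -> 32
    filtering chain.

Sparse missingness can be applied to match the panel's per-locus call
counts exactly. Every mode records its latent truth (frequencies, labels,
IBD coefficients, seed) alongside the genotype table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import MISSING, GenotypeTable
from . import sim as island_sim

__all__ = ["Table2Locus", "Table2Panel", "GeneratorSpec",
           "table2_frequencies", "generate", "sibship"]


@dataclass(frozen=True)
class Table2Locus:
    locus_id: str
    linkage_group: int
    he_printed: float
    n_genotypes: int
    major_allele: str
    major_freq: float
    minor_allele: str
    minor_freq_printed: float
    hwe_p_printed: float
    freq_repaired: bool = False
    he_inconsistent: bool = False

    @property
    def minor_freq(self) -> float:
        """Minor frequency with the typographic repair 1 - major applied."""
        return round(1.0 - self.major_freq, 3)


@dataclass(frozen=True)
class Table2Panel:
    loci: tuple[Table2Locus, ...]

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, locus_id: str) -> Table2Locus:
        for rec in self.loci:
            if rec.locus_id == locus_id:
                return rec
        raise KeyError(locus_id)

    @property
    def minor_freqs(self) -> np.ndarray:
        return np.array([rec.minor_freq for rec in self.loci])


# marker, LG, He, n, major, p_major, minor, p_minor, P(HWE)
_PANEL_ROWS = [
    ("24644", 1, 0.09, 159, "C", 0.95, "A", 0.05, 1.00),
    ("29372", 1, 0.34, 157, "A", 0.78, "G", 0.22, 0.16),
    ("28629", 2, 0.01, 159, "A", 0.99, "G", 0.01, 1.00),
    ("29012", 2, 0.49, 158, "C", 0.57, "T", 0.43, 0.87),
    ("2438", 3, 0.41, 158, "T", 0.71, "C", 0.29, 0.34),
    ("16185", 4, 0.43, 159, "T", 0.69, "G", 0.31, 0.85),
    ("4544", 5, 0.07, 159, "G", 0.96, "A", 0.04, 0.19),
    ("17562", 5, 0.15, 159, "T", 0.92, "C", 0.02, 0.31),
    ("31597", 6, 0.35, 159, "T", 0.76, "C", 0.24, 0.83),
    ("24214", 8, 0.50, 158, "A", 0.50, "C", 0.50, 0.27),
    ("25808", 8, 0.15, 159, "G", 0.92, "T", 0.08, 0.60),
    ("29227", 8, 0.47, 158, "T", 0.62, "A", 0.38, 0.18),
    ("20626", 9, 0.46, 159, "A", 0.63, "G", 0.27, 0.24),
    ("18083", 10, 0.49, 159, "T", 0.57, "C", 0.43, 0.02),
    ("29288", 10, 0.16, 159, "G", 0.91, "A", 0.01, 0.62),
    ("19045", 11, 0.01, 159, "A", 0.997, "G", 0.003, 1.00),
    ("9694", 13, 0.26, 159, "C", 0.85, "T", 0.15, 0.36),
    ("7972", 14, 0.35, 159, "G", 0.77, "C", 0.23, 1.00),
    ("31404", 14, 0.42, 159, "C", 0.70, "A", 0.30, 1.00),
    ("12169", 15, 0.47, 159, "C", 0.62, "T", 0.38, 1.00),
    ("27696", 15, 0.12, 159, "T", 0.94, "C", 0.06, 0.47),
    ("31328", 15, 0.07, 159, "T", 0.93, "C", 0.07, 1.00),
    ("13903", 16, 0.34, 150, "T", 0.78, "C", 0.22, 0.64),
    ("13738", 17, 0.07, 158, "C", 0.96, "T", 0.04, 1.00),
    ("18241", 17, 0.02, 159, "G", 0.99, "C", 0.01, 1.00),
    ("34117", 17, 0.34, 158, "C", 0.78, "T", 0.22, 1.00),
    ("4106", 18, 0.02, 159, "C", 0.99, "G", 0.01, 1.00),
    ("24550", 19, 0.37, 159, "A", 0.75, "G", 0.25, 0.52),
    ("25627", 19, 0.49, 159, "G", 0.55, "T", 0.45, 0.52),
    ("27998", 19, 0.34, 159, "G", 0.79, "A", 0.21, 0.81),
    ("13161", 20, 0.48, 159, "G", 0.59, "A", 0.41, 0.62),
    ("16861", 21, 0.49, 159, "G", 0.56, "A", 0.44, 0.11),
]

# rows whose printed frequency pair does not sum to 1
_FREQ_REPAIRED = {"17562", "29288", "19045", "20626"}
# row whose printed He disagrees with its own frequency pair (2pq = 0.13)
_HE_INCONSISTENT = {"31328"}


def table2_frequencies() -> Table2Panel:
    """The built-in 32-locus panel with typographic repairs flagged."""
    loci = tuple(
        Table2Locus(
            locus_id=m, linkage_group=lg, he_printed=he, n_genotypes=n,
            major_allele=maj, major_freq=pmaj, minor_allele=mnr,
            minor_freq_printed=pmnr, hwe_p_printed=hwe,
            freq_repaired=m in _FREQ_REPAIRED,
            he_inconsistent=m in _HE_INCONSISTENT,
        )
        for m, lg, he, n, maj, pmaj, mnr, pmnr, hwe in _PANEL_ROWS
    )
    return Table2Panel(loci=loci)


@dataclass
class GeneratorSpec:
    mode: str = "panmictic"
    group_sizes: tuple[int, ...] = (55, 55, 49)
    fst: Optional[float] = None            # structured modes
    relationship: str = "unrelated"        # pedigree mode
    n_dyads: int = 500                     # pedigree mode
    n_loci: Optional[int] = None           # override (non-panel loci)
    match_missingness: bool = False        # thin calls to panel counts
    island_deme_size: int = 1500
    island_n_loci: int = 3150
    island_burn_in: Optional[int] = None
    seed: int = 0

    _MODES = ("panmictic", "balding_nichols", "island_forward",
              "pedigree_dyads", "qc_fixture")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in ("balding_nichols", "island_forward") and not self.fst:
            raise ValueError(f"mode {self.mode!r} needs a target fst")
        if self.relationship not in ("unrelated", "parent_offspring",
                                     "full_sib"):
            raise ValueError(f"unknown relationship {self.relationship!r}")


_GROUP_ORDER = ("benthic", "littoral", "pelagic")
_IBD_TRUTH = {
    "unrelated": (1.0, 0.0, 0.0),
    "parent_offspring": (0.0, 1.0, 0.0),
    "full_sib": (0.25, 0.5, 0.25),
}


def _locus_symbols(panel: Table2Panel, n_loci: Optional[int]):
    """Locus ids, alleles and linkage groups: the panel's own, or generic."""
    if n_loci is None or n_loci == len(panel):
        ids = [r.locus_id for r in panel]
        major = [r.major_allele for r in panel]
        minor = [r.minor_allele if r.minor_allele != r.major_allele else "T"
                 for r in panel]
        lg = [r.linkage_group for r in panel]
    else:
        ids = [f"L{k:04d}" for k in range(n_loci)]
        major = ["A"] * n_loci
        minor = ["G"] * n_loci
        lg = [0] * n_loci
    return ids, major, minor, lg


def _calls_from_dosage(dos: np.ndarray, major: list[str],
                       minor: list[str]) -> np.ndarray:
    n, L = dos.shape
    calls = np.empty((n, L), dtype=object)
    for j in range(L):
        sym = {
            0: "".join(sorted(major[j] + major[j])),
            1: "".join(sorted(major[j] + minor[j])),
            2: "".join(sorted(minor[j] + minor[j])),
        }
        for i in range(n):
            g = dos[i, j]
            calls[i, j] = MISSING if g < 0 else sym[int(g)]
    return calls


def _metadata(n: int) -> tuple[list[str], list[int]]:
    sample_ids = [f"S{k + 1:03d}" for k in range(n)]
    batch = [1 if k < (n + 1) // 2 else 2 for k in range(n)]
    return sample_ids, batch


def _habitats(group_sizes: tuple[int, ...]) -> list[str]:
    out: list[str] = []
    for g, size in enumerate(group_sizes):
        out.extend([_GROUP_ORDER[g % 3]] * size)
    return out


def _apply_missingness(dos: np.ndarray, panel: Table2Panel,
                       rng: np.random.Generator) -> None:
    n = dos.shape[0]
    for j, rec in enumerate(panel):
        n_missing = n - rec.n_genotypes
        if n_missing > 0:
            rows = rng.choice(n, n_missing, replace=False)
            dos[rows, j] = -1


def generate(spec: GeneratorSpec) -> tuple[GenotypeTable, dict]:
    """Generate a genotype table plus a truth record for the given spec."""
    rng = np.random.default_rng(spec.seed)
    panel = table2_frequencies()
    truth: dict = {"mode": spec.mode, "seed": spec.seed}

    if spec.mode == "pedigree_dyads":
        return _generate_dyads(spec, panel, rng, truth)
    if spec.mode == "qc_fixture":
        return _generate_qc_fixture(spec, rng, truth)

    n = sum(spec.group_sizes)
    ids, major, minor, lg = _locus_symbols(panel, spec.n_loci)
    L = len(ids)

    if spec.mode == "panmictic":
        q = panel.minor_freqs if spec.n_loci in (None, len(panel)) else \
            rng.uniform(0.1, 0.9, size=L)
        dos = rng.binomial(2, q, size=(n, L)).astype(np.int8)
        truth["minor_freqs"] = q.tolist()
    elif spec.mode == "balding_nichols":
        q = panel.minor_freqs if spec.n_loci in (None, len(panel)) else \
            rng.uniform(0.1, 0.9, size=L)
        lam = (1.0 - spec.fst) / spec.fst
        group_q = rng.beta(q * lam, (1.0 - q) * lam,
                           size=(len(spec.group_sizes), L))
        parts = [
            rng.binomial(2, group_q[g], size=(size, L)).astype(np.int8)
            for g, size in enumerate(spec.group_sizes)
        ]
        dos = np.vstack(parts)
        truth["ancestral_minor_freqs"] = q.tolist()
        truth["group_minor_freqs"] = group_q.tolist()
        truth["target_fst"] = spec.fst
        truth["realized_fst"] = island_sim.parametric_fst(group_q)
    else:  # island_forward
        m = island_sim.wright_island_m(spec.fst, spec.island_deme_size,
                                       len(spec.group_sizes))
        cfg = island_sim.IslandConfig(
            n_demes=len(spec.group_sizes),
            deme_size=spec.island_deme_size,
            n_loci=spec.island_n_loci,
            migration_rate=m,
            burn_in_generations=spec.island_burn_in,
            seed=spec.seed,
        )
        pop = island_sim.simulate_island(cfg)
        pooled = pop.freqs.mean(axis=0)
        poly = np.flatnonzero((pooled > 0) & (pooled < 1))
        loci = np.sort(rng.choice(poly, L, replace=False))
        rows = np.concatenate([
            np.flatnonzero(pop.deme == g)[
                rng.choice(spec.island_deme_size, size, replace=False)]
            for g, size in enumerate(spec.group_sizes)
        ])
        dos = pop.values[np.ix_(rows, loci)].astype(np.int8)
        truth["migration_rate"] = m
        truth["realized_fst"] = pop.realized_fst
        truth["target_fst"] = spec.fst
        truth["loci_sampled"] = loci.tolist()

    if spec.match_missingness and L == len(panel):
        _apply_missingness(dos, panel, rng)
    truth["dosages"] = dos.tolist()

    sample_ids, batch = _metadata(n)
    table = GenotypeTable(
        sample_ids=sample_ids,
        habitat=_habitats(spec.group_sizes),
        batch=batch,
        locus_ids=ids,
        linkage_group=lg,
        calls=_calls_from_dosage(dos, major, minor),
    )
    return table, truth


def _generate_dyads(spec, panel, rng, truth):
    q = panel.minor_freqs
    L = len(panel)
    nd = spec.n_dyads
    if spec.relationship == "unrelated":
        a = rng.binomial(2, q, size=(nd, L))
        b = rng.binomial(2, q, size=(nd, L))
    elif spec.relationship == "parent_offspring":
        a = rng.binomial(2, q, size=(nd, L))
        from_parent = rng.binomial(1, a / 2.0)
        from_pop = rng.binomial(1, np.broadcast_to(q, (nd, L)))
        b = from_parent + from_pop
    else:  # full_sib
        p1 = rng.binomial(2, q, size=(nd, L))
        p2 = rng.binomial(2, q, size=(nd, L))
        a = rng.binomial(1, p1 / 2.0) + rng.binomial(1, p2 / 2.0)
        b = rng.binomial(1, p1 / 2.0) + rng.binomial(1, p2 / 2.0)
    dos = np.empty((2 * nd, L), dtype=np.int8)
    dos[0::2] = a
    dos[1::2] = b
    truth.update(
        relationship=spec.relationship,
        ibd_coefficients=_IBD_TRUTH[spec.relationship],
        r=_IBD_TRUTH[spec.relationship][2]
        + _IBD_TRUTH[spec.relationship][1] / 2.0,
        minor_freqs=q.tolist(),
        pairs=[[2 * k, 2 * k + 1] for k in range(nd)],
    )
    ids, major, minor, lg = _locus_symbols(panel, None)
    sample_ids, batch = _metadata(2 * nd)
    table = GenotypeTable(
        sample_ids=sample_ids,
        habitat=["littoral"] * (2 * nd),
        batch=batch,
        locus_ids=ids,
        linkage_group=lg,
        calls=_calls_from_dosage(dos, major, minor),
    )
    return table, truth


def _generate_qc_fixture(spec, rng, truth):
    """55 loci: 22 monomorphic, 32 clean polymorphic, 1 gross HWE violation."""
    n = sum(spec.group_sizes)
    n_mono, n_poly = 22, 33
    L = n_mono + n_poly
    q = rng.uniform(0.1, 0.5, size=L)
    dos = rng.binomial(2, q, size=(n, L)).astype(np.int8)
    mono_idx = rng.choice(L, n_mono, replace=False)
    dos[:, mono_idx] = 0
    poly_idx = np.setdiff1d(np.arange(L), mono_idx)
    hwe_idx = int(poly_idx[0])
    dos[:, hwe_idx] = 1  # all heterozygous: extreme HWE excess
    truth.update(
        monomorphic_loci=sorted(int(i) for i in mono_idx),
        hwe_violation_locus=hwe_idx,
        minor_freqs=q.tolist(),
    )
    ids = [f"Q{k:04d}" for k in range(L)]
    sample_ids, batch = _metadata(n)
    table = GenotypeTable(
        sample_ids=sample_ids,
        habitat=_habitats(spec.group_sizes),
        batch=batch,
        locus_ids=ids,
        linkage_group=[0] * L,
        calls=_calls_from_dosage(dos, ["A"] * L, ["G"] * L),
    )
    return table, truth


def sibship(n_sibs: int, seed: int = 0) -> tuple[GenotypeTable, dict]:
    """One full-sib family: two founders drawn at panel frequencies and
    ``n_sibs`` offspring by Mendelian transmission (every offspring pair has
    expected relatedness 0.5). Useful as a planted positive control for the
    within-group coancestry test."""
    rng = np.random.default_rng(seed)
    panel = table2_frequencies()
    q = panel.minor_freqs
    L = len(panel)
    p1 = rng.binomial(2, q)
    p2 = rng.binomial(2, q)
    dos = (rng.binomial(1, np.tile(p1 / 2.0, (n_sibs, 1)))
           + rng.binomial(1, np.tile(p2 / 2.0, (n_sibs, 1)))).astype(np.int8)
    ids, major, minor, lg = _locus_symbols(panel, None)
    sample_ids, batch = _metadata(n_sibs)
    table = GenotypeTable(
        sample_ids=sample_ids,
        habitat=["littoral"] * n_sibs,
        batch=batch,
        locus_ids=ids,
        linkage_group=lg,
        calls=_calls_from_dosage(dos, major, minor),
    )
    truth = {"mode": "sibship", "seed": seed, "n_sibs": n_sibs,
             "parent_dosages": [p1.tolist(), p2.tolist()],
             "r": 0.5, "ibd_coefficients": (0.25, 0.5, 0.25)}
    return table, truth
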