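"""Seeded synthetic-data generators emulating each assay's statistical structure.

Every generator is deterministic under a fixed seed and configuration and
emits exactly the schemas the analysis modules consume, so the whole
pipeline is testable without any wet-lab input:

* :func:`gen_reveal_dataset` -- exponential peptide--HLA signal decay
  (two-timepoint binding scores with optional multiplicative noise);
* :func:`gen_titration` -- one-site equilibrium dextramer binding on the
  standard 8-point dilution design with optional lognormal noise and
  additive background;
* :func:`gen_repertoire` -- clonally expanded paired-chain repertoires with
  planted clone sizes, background singletons and optional low-UMI duplicate
  chains to exercise contig filtering;
* :func:`gen_counts` -- negative-binomial gene-by-cell counts with planted
  fold-changes between a clonotype group and the rest;
* :func:`gen_in_vivo` -- per-glomerulus / per-field renal-injury events and
  dipstick proteinuria readings with group-specific probabilities.

Noise models follow each readout's support: multiplicative lognormal for
fluorescence, Bernoulli/Poisson for histology events and counts per
cross-section, negative binomial for transcript counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .affinity import TitrationSeries, dilution_series, one_site_bound
from .repertoire import CONTIG_COLUMNS

__all__ = [
    "GeneratorConfig",
    "gen_reveal_dataset",
    "gen_titration",
    "gen_repertoire",
    "gen_counts",
    "gen_in_vivo",
    "generate",
    "IN_VIVO_GROUPS",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"

#: Default in vivo scenario: one entry per treatment group with the event
#: probabilities / means used to draw per-glomerulus and per-field injury
#: and dipstick proteinuria.  The three disease groups use the published
#: week-8 group means of the humanized lupus-nephritis model (necrosis %,
#: cells/gcs, mesangial %, tubulointerstitial %, mean proteinuria score);
#: the healthy-cell control group, whose histology means are not printed,
#: uses near-zero event rates and a normal cell count.
IN_VIVO_GROUPS: dict[str, dict[str, float]] = {
    "no_treg": dict(
        n_mice=5, necrosis_p=0.752, cells_mean=39.8, mesangial_p=0.62,
        hpf_p=0.50, proteinuria_mean=3.6,
    ),
    "ptreg": dict(
        n_mice=5, necrosis_p=0.612, cells_mean=37.8, mesangial_p=0.59,
        hpf_p=0.50, proteinuria_mean=3.2,
    ),
    "sm_treg": dict(
        n_mice=5, necrosis_p=0.144, cells_mean=25.8, mesangial_p=0.14,
        hpf_p=0.10, proteinuria_mean=1.2,
    ),
    "healthy": dict(
        n_mice=4, necrosis_p=0.01, cells_mean=20.0, mesangial_p=0.01,
        hpf_p=0.01, proteinuria_mean=0.25,
    ),
}

_SCORE_TO_READING: dict[int, str | float] = {0: "trace", 1: 0.30, 2: 1.0, 3: 3.0, 4: 20.0}


@dataclass(frozen=True)
class GeneratorConfig:
    """A named simulation scenario: seed plus scenario-specific parameters."""

    seed: int
    scenario: str  # one of: reveal, titration, repertoire, counts, in_vivo
    parameters: dict[str, Any] = field(default_factory=dict)


def generate(cfg: GeneratorConfig):
    """Dispatch a :class:`GeneratorConfig` to its generator."""
    dispatch = {
        "reveal": gen_reveal_dataset,
        "titration": gen_titration,
        "repertoire": gen_repertoire,
        "counts": gen_counts,
        "in_vivo": gen_in_vivo,
    }
    if cfg.scenario not in dispatch:
        raise ValueError(
            f"unknown scenario {cfg.scenario!r}; expected one of {sorted(dispatch)}"
        )
    return dispatch[cfg.scenario](seed=cfg.seed, **cfg.parameters)


def _tile_names(n: int, parent_id: str, k: int = 15, offset: int = 3) -> list[str]:
    return [f"{parent_id}_{1 + i * offset}-{i * offset + k}" for i in range(n)]


def gen_reveal_dataset(
    seed: int = 0,
    n_peptides: int = 145,
    half_lives: Sequence[float] | None = None,
    y0: Sequence[float] | None = None,
    t: float = 24.0,
    noise_cv: float = 0.0,
    parent_id: str = "SYN",
) -> pd.DataFrame:
    """Two-timepoint binding scores under one-phase exponential decay.

    Each peptide decays as ``y_t = y0 * 2**(-t / h)`` with half-life ``h``;
    ``noise_cv`` applies multiplicative lognormal noise to the late read.
    When half-lives / initial scores are not supplied they are drawn
    lognormally (median half-life 6 h, median initial score 20% of the
    positive control), mimicking a screen in which most tiles bind weakly.
    Peptide names follow the 15-mer/offset-3 tiling convention.
    """
    rng = np.random.default_rng(seed)
    if half_lives is None:
        half_lives = np.exp(rng.normal(np.log(6.0), 0.8, size=n_peptides))
    h = np.asarray(half_lives, dtype=float)
    if np.any(h <= 0):
        raise ValueError("half-lives must be > 0")
    n = h.size
    if y0 is None:
        y0 = np.exp(rng.normal(np.log(20.0), 1.0, size=n))
    y0_arr = np.asarray(y0, dtype=float)
    if y0_arr.size != n:
        raise ValueError("y0 and half_lives must have the same length")
    if np.any(y0_arr < 0):
        raise ValueError("initial scores must be >= 0")
    y24 = y0_arr * 2.0 ** (-t / h)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        y24 = y24 * rng.lognormal(-(sigma**2) / 2, sigma, size=n)
    return pd.DataFrame(
        {"peptide_name": _tile_names(n, parent_id), "y0": y0_arr, "y24": y24, "t": t}
    )


def gen_titration(
    seed: int = 0,
    kd: float = 1.0,
    bmax: float = 1000.0,
    start: float = 5.0,
    n_dilutions: int = 7,
    factor: float = 2.0,
    include_zero: bool = True,
    noise_cv: float = 0.0,
    background: float = 0.0,
    label: str = "dextramer",
) -> TitrationSeries:
    """One-site saturation-binding MFI on a serial-dilution design.

    The default design is the standard dextramer titration: seven twofold
    dilutions from 5 nM plus a 0 nM background well.  ``noise_cv`` applies
    multiplicative lognormal noise to the specific bound signal;
    ``background`` is added to every well (the 0 nM well then reads
    background alone).
    """
    rng = np.random.default_rng(seed)
    conc = np.array(dilution_series(start, n_dilutions, factor, include_zero))
    bound = one_site_bound(conc, kd=kd, bmax=bmax)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        bound = bound * rng.lognormal(-(sigma**2) / 2, sigma, size=conc.size)
    return TitrationSeries(label=label, concentrations=conc, mfi=bound + background)


def _random_cdr3_nt(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        length = 3 * int(rng.integers(10, 16))
        s = "".join(rng.choice(list(_NT), size=length))
        if s not in used:
            used.add(s)
            return s


def _random_chain(rng: np.random.Generator, locus: str, used: set[str]) -> dict[str, str]:
    cdr3_nt = _random_cdr3_nt(rng, used)
    cdr3_aa = "C" + "".join(rng.choice(list(_AA), size=len(cdr3_nt) // 3 - 2)) + "F"
    return {
        "chain": locus,
        "v_gene": f"{locus}V{int(rng.integers(1, 31))}",
        "j_gene": f"{locus}J{int(rng.integers(1, 13))}",
        "cdr3_aa": cdr3_aa,
        "cdr3_nt": cdr3_nt,
    }


def gen_repertoire(
    seed: int = 42,
    clone_sizes: Sequence[int] = (59, 16, 13),
    n_singletons: int = 200,
    n_low_umi_duplicates: int = 0,
    n_unpaired: int = 0,
    n_nonproductive: int = 0,
) -> pd.DataFrame:
    """Contig table for a repertoire with planted clonal expansions.

    Plants one clonotype per entry of ``clone_sizes`` (each clonotype's
    cells share identical TRA and TRB V/J genes and nucleotide CDR3s) plus
    ``n_singletons`` unique background clonotypes.  Every cell carries one
    productive high-confidence TRA and TRB contig.  Optional contamination
    exercises the filtering rules: ``n_low_umi_duplicates`` cells receive an
    extra lower-UMI TRB contig, ``n_unpaired`` extra cells carry a TRB only,
    and ``n_nonproductive`` cells gain a non-productive contig.
    """
    clone_sizes = [int(s) for s in clone_sizes]
    if any(s < 1 for s in clone_sizes):
        raise ValueError("clone sizes must be >= 1")
    rng = np.random.default_rng(seed)
    used_cdr3: set[str] = set()
    used_barcodes: set[str] = set()

    def new_barcode() -> str:
        while True:
            bc = "".join(rng.choice(list(_NT), size=16)) + "-1"
            if bc not in used_barcodes:
                used_barcodes.add(bc)
                return bc

    rows: list[dict] = []

    def add_cell(tra: dict, trb: dict) -> str:
        bc = new_barcode()
        for ch in (tra, trb):
            rows.append(
                {
                    "barcode": bc,
                    **ch,
                    "productive": True,
                    "high_confidence": True,
                    "umis": int(rng.integers(4, 40)),
                }
            )
        return bc

    barcodes: list[str] = []
    for size in clone_sizes:
        tra = _random_chain(rng, "TRA", used_cdr3)
        trb = _random_chain(rng, "TRB", used_cdr3)
        for _ in range(size):
            barcodes.append(add_cell(tra, trb))
    for _ in range(n_singletons):
        barcodes.append(
            add_cell(_random_chain(rng, "TRA", used_cdr3), _random_chain(rng, "TRB", used_cdr3))
        )

    # contamination: extra low-UMI duplicate TRB chains on existing cells
    dup_targets = rng.choice(len(barcodes), size=min(n_low_umi_duplicates, len(barcodes)), replace=False)
    for idx in dup_targets:
        rows.append(
            {
                "barcode": barcodes[idx],
                **_random_chain(rng, "TRB", used_cdr3),
                "productive": True,
                "high_confidence": True,
                "umis": 1,  # below the planted chains' minimum of 4
            }
        )
    for _ in range(n_unpaired):
        rows.append(
            {
                "barcode": new_barcode(),
                **_random_chain(rng, "TRB", used_cdr3),
                "productive": True,
                "high_confidence": True,
                "umis": int(rng.integers(4, 40)),
            }
        )
    nonprod_targets = rng.choice(len(barcodes), size=min(n_nonproductive, len(barcodes)), replace=False)
    for idx in nonprod_targets:
        rows.append(
            {
                "barcode": barcodes[idx],
                **_random_chain(rng, "TRA", used_cdr3),
                "productive": False,
                "high_confidence": True,
                "umis": int(rng.integers(4, 40)),
            }
        )
    return pd.DataFrame(rows, columns=CONTIG_COLUMNS)


def gen_counts(
    seed: int = 0,
    n_genes: int = 2000,
    n_cells_a: int = 20,
    n_cells_b: int = 20,
    mean_log: float = np.log(5.0),
    mean_log_sd: float = 1.0,
    dispersion: float = 0.15,
    fold_change: float = 1.0,
    n_de_genes: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """NB gene-by-cell counts with planted fold-changes.

    Per-gene base means are lognormal (median ``exp(mean_log)``); every
    gene shares ``dispersion``.  The first ``n_de_genes`` genes (named
    ``DEG...``) have their group-A mean multiplied by ``fold_change``;
    the remainder (``G...``) are null.

    Returns
    -------
    (counts, groups)
        ``counts`` is a genes x cells integer DataFrame; ``groups`` maps
        cell -> ``"clonotype"`` (group A) or ``"rest"``.
    """
    if n_de_genes > n_genes:
        raise ValueError("n_de_genes cannot exceed n_genes")
    if dispersion < 0 or fold_change <= 0:
        raise ValueError("dispersion must be >= 0 and fold_change > 0")
    rng = np.random.default_rng(seed)
    base_mu = np.exp(rng.normal(mean_log, mean_log_sd, size=n_genes))
    mu_a = base_mu.copy()
    mu_a[:n_de_genes] *= fold_change
    mu_b = base_mu

    def draw(mu: np.ndarray, n_cells: int) -> np.ndarray:
        m = np.repeat(mu[:, None], n_cells, axis=1)
        if dispersion == 0:
            return rng.poisson(m)
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + m))

    counts = np.hstack([draw(mu_a, n_cells_a), draw(mu_b, n_cells_b)])
    genes = [f"DEG{i:04d}" if i < n_de_genes else f"G{i:04d}" for i in range(n_genes)]
    cells = [f"cellA{i:04d}" for i in range(n_cells_a)] + [
        f"cellB{i:04d}" for i in range(n_cells_b)
    ]
    df = pd.DataFrame(counts, index=genes, columns=cells)
    groups = pd.Series(
        ["clonotype"] * n_cells_a + ["rest"] * n_cells_b, index=cells, name="group"
    )
    return df, groups


def gen_in_vivo(
    seed: int = 0,
    groups: dict[str, dict[str, float]] | None = None,
    n_glomeruli: int = 50,
    n_hpf: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic humanized-mouse nephritis cohort, one kidney per mouse.

    For each group (default :data:`IN_VIVO_GROUPS`): per-glomerulus
    necrosis is Bernoulli(``necrosis_p``) expressed as a PAS-positive
    fraction above/below the 0.5 scoring threshold; mesangial clumping is
    Bernoulli(``mesangial_p``) expressed as a clump size at/above 3; cell
    counts are Poisson(``cells_mean``); each hpf flags injury with
    probability ``hpf_p``; the ordinal proteinuria score is drawn as
    Binomial(4, mean/4) -- whose mean is exactly ``proteinuria_mean`` --
    and emitted as the corresponding dipstick reading (g/L or "trace").
    Crescents are not generated (Bowman layer count 1), matching their
    absence in the modelled disease course.

    Returns
    -------
    (glomeruli, hpfs, proteinuria)
        Three DataFrames keyed by ``kidney_id`` and ``group``, with the
        per-glomerulus columns of
        :class:`~immunoquant.histology.GlomerulusObservation`, the
        per-field flags of :class:`~immunoquant.histology.HpfObservation`,
        and dipstick ``reading`` / derived ``score`` columns respectively.
    """
    cfg = groups if groups is not None else IN_VIVO_GROUPS
    rng = np.random.default_rng(seed)
    glom_rows, hpf_rows, prot_rows = [], [], []
    for group, params in cfg.items():
        for mouse in range(int(params["n_mice"])):
            kid = f"{group}_m{mouse + 1}"
            necrotic = rng.random(n_glomeruli) < params["necrosis_p"]
            mesangial = rng.random(n_glomeruli) < params["mesangial_p"]
            cells = rng.poisson(params["cells_mean"], size=n_glomeruli)
            for i in range(n_glomeruli):
                glom_rows.append(
                    {
                        "kidney_id": kid,
                        "group": group,
                        # express the event as a fraction on the correct side
                        # of the 0.5 scoring threshold
                        "pas_positive_fraction": round(
                            float(rng.uniform(0.5, 1.0) if necrotic[i] else rng.uniform(0.0, 0.5 - 1e-6)),
                            6,
                        ),
                        "cell_count": int(cells[i]),
                        "max_clumped_nuclei": int(rng.integers(3, 8)) if mesangial[i] else int(rng.integers(0, 3)),
                        "bowman_cell_layers": 1,
                    }
                )
            injured = rng.random(n_hpf) < params["hpf_p"]
            for i in range(n_hpf):
                kinds = rng.random(4) < 0.5 if injured[i] else np.zeros(4, dtype=bool)
                if injured[i] and not kinds.any():
                    kinds[int(rng.integers(0, 4))] = True
                hpf_rows.append(
                    {
                        "kidney_id": kid,
                        "group": group,
                        "infiltrate": bool(kinds[0]),
                        "tubular_dilation": bool(kinds[1]),
                        "necrosis": bool(kinds[2]),
                        "protein_casts": bool(kinds[3]),
                    }
                )
            score = int(rng.binomial(4, params["proteinuria_mean"] / 4.0))
            prot_rows.append(
                {
                    "kidney_id": kid,
                    "group": group,
                    "reading": _SCORE_TO_READING[score],
                    "score": score,
                }
            )
    return pd.DataFrame(glom_rows), pd.DataFrame(hpf_rows), pd.DataFrame(prot_rows)
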