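"""Synthetic inputs with the geometric and statistical structure the
analysis assumes, so every stage is testable without downloads.

Three generators, all driven by one global seed (per-stage substreams
are derived deterministically):

* :func:`make_toy_complex` — a two-chain pseudo-protein: each chain is a
  jittered lattice block of C-alpha pseudo-atoms whose facing layers sit
  within contact distance, so the true cross-chain contact set is known
  by construction and emitted alongside the structure;
* :func:`simulate_savs` — variant tables with per-region binomial
  placement at configurable rates (defaults: the per-region rates of the
  reference survey counts);
* :func:`simulate_ddg` — alanine-scan energies from a two-component
  mixture (folded normal below 1 kcal/mol plus a shifted exponential
  tail) calibrated analytically so the expected exceedance fractions
  P(ddG >= 1) and P(ddG >= 2) match configured targets; defaults match
  the reference survey's core (42.5% / 20.3%) and rim (23.2% / 8.9%)
  fractions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aminoacids import ONE_TO_THREE
from .reference_data import OBSERVED, REGION_TOTALS
from .structure import Atom, Complex, Residue

_AA_CYCLE = "ARNDCQEGHILKMFPSTWYV"


class ConfigError(ValueError):
    """Simulation configuration violates a feasibility constraint."""


def _default_rates(category: str) -> dict[str, float]:
    return {r: OBSERVED[category][r] / REGION_TOTALS[r] for r in REGION_TOTALS}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generators.

    Geometry: each chain is an ``nx x ny x nz`` lattice of C-alpha
    pseudo-atoms with ``spacing`` (A) between neighbours and ``gap`` (A)
    between the two facing layers; ``jitter`` perturbs positions
    uniformly in ``[-jitter, jitter]`` per coordinate (small enough to
    preserve the designed contact pattern).
    """

    seed: int = 0
    # toy-complex geometry
    nx: int = 4
    ny: int = 4
    nz: int = 3
    spacing: float = 4.0
    gap: float = 4.5
    jitter: float = 0.15
    # variant placement
    region_sizes: dict[str, int] = field(
        default_factory=lambda: dict(REGION_TOTALS))
    disease_rates: dict[str, float] = field(
        default_factory=lambda: _default_rates("disease"))
    polymorphism_rates: dict[str, float] = field(
        default_factory=lambda: _default_rates("polymorphism"))
    # ddG exceedance targets per region: (P(>=1 kcal/mol), P(>=2 kcal/mol))
    ddg_exceedance: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"core": (0.425, 0.203), "rim": (0.232, 0.089)})
    ddg_baseline_sd: float = 0.4
    ddg_mut_slope: float = 0.7
    ddg_mut_noise_sd: float = 0.8

    def __post_init__(self) -> None:
        for rates in (self.disease_rates, self.polymorphism_rates):
            for r, p in rates.items():
                if not 0 <= p <= 1:
                    raise ConfigError(f"rate outside [0, 1] for region {r!r}")
        for n in self.region_sizes.values():
            if n <= 0:
                raise ConfigError("region sizes must be positive")
        for region, (p1, p2) in self.ddg_exceedance.items():
            if not (0 < p2 < p1 < 1):
                raise ConfigError(
                    f"infeasible exceedance targets for {region!r}: "
                    f"need 0 < P(>=2) < P(>=1) < 1, got ({p1}, {p2})")

    def substreams(self, n: int = 4) -> list[np.random.Generator]:
        seqs = np.random.SeedSequence(self.seed).spawn(n)
        return [np.random.default_rng(s) for s in seqs]


# ---------------------------------------------------------------------------
# toy complex

def make_toy_complex(config: SimulationConfig | None = None,
                     ) -> tuple[Complex, set[tuple]]:
    """Deterministic two-chain pseudo-protein plus its ground-truth
    cross-chain contact list.

    Chain A occupies lattice layers below the interface plane and chain
    B the layers above it, ``gap`` apart; with default spacing the only
    cross-chain pairs within 5 A are vertically aligned facing-layer
    residues, which form the emitted truth set.  Raises
    :class:`ConfigError` if the requested geometry brings the chains
    into clashing contact.
    """
    cfg = config or SimulationConfig()
    j2 = 2 * cfg.jitter
    if cfg.gap - j2 * math.sqrt(3) <= 2.0:
        raise ConfigError("chains clash: gap too small for the jitter level")
    if cfg.gap <= 5.0:
        # worst-case jitter must neither push aligned facing pairs out of
        # contact range nor pull laterally offset pairs into it
        aligned_max = math.sqrt(2 * j2 * j2 + (cfg.gap + j2) ** 2)
        offset_min = math.sqrt((cfg.spacing - j2) ** 2 + (cfg.gap - j2) ** 2)
        if aligned_max > 5.0 or offset_min <= 5.0:
            raise ConfigError("geometry does not guarantee the designed contact set")
    rng = cfg.substreams()[0]
    aa_iter = itertools.cycle(_AA_CYCLE)

    def build_chain(chain_id: str, z0: float, flip: bool) -> list[Residue]:
        residues = []
        num = 0
        # layer order: interface-facing layer is z-index 0
        for iz, iy, ix in itertools.product(range(cfg.nz), range(cfg.ny), range(cfg.nx)):
            num += 1
            z = z0 + (iz * cfg.spacing) * (1 if flip else -1)
            x, y = ix * cfg.spacing, iy * cfg.spacing
            dx, dy, dz = rng.uniform(-cfg.jitter, cfg.jitter, size=3)
            atom = Atom(element="C", name="CA",
                        coords=(x + dx, y + dy, z + dz), vdw_radius=1.70)
            residues.append(Residue(
                chain_id=chain_id, seq_number=num, insertion_code="",
                aa_type=next(aa_iter), atoms=(atom,)))
        return residues

    chain_a = build_chain("A", 0.0, flip=False)
    chain_b = build_chain("B", cfg.gap, flip=True)
    cx = Complex(identifier="toy", chains={"A": chain_a, "B": chain_b})

    contacts: set[tuple] = set()
    if cfg.gap <= 5.0:
        per_layer = cfg.nx * cfg.ny
        for i in range(per_layer):  # facing layers are the first per_layer residues
            contacts.add((chain_a[i].key, chain_b[i].key))
    return cx, contacts


def to_pdb_text(complex: Complex) -> str:
    """Minimal, deterministic PDB serialisation (ATOM records + TER/END)."""
    lines = []
    serial = 0
    for cid, residues in complex.chains.items():
        for res in residues:
            res3 = ONE_TO_THREE[res.aa_type]
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {atom.name:^4s}{res3:>4s} {cid:1s}"
                    f"{res.seq_number:4d}{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# variant tables

def simulate_counts(
    region_sizes: dict[str, int],
    rates: dict[str, float],
    rng: np.random.Generator,
) -> dict[str, int]:
    """Per-region variant counts, binomial at the configured rates.

    The count-level core of :func:`simulate_savs`; used directly by
    replicate experiments that do not need per-variant rows.
    """
    return {
        region: int(rng.binomial(n, rates.get(region, 0.0)))
        for region, n in region_sizes.items()
    }


def simulate_savs(config: SimulationConfig | None = None) -> pd.DataFrame:
    """Synthetic variant table: per region and category, a binomial
    number of variants at the configured rate; wild-type/mutant pairs
    uniform over distinct ordered pairs.

    Columns: gene, accession, change, category, region (ground truth).
    """
    cfg = config or SimulationConfig()
    rng = cfg.substreams()[1]
    rows = []
    idx = 0
    for category, rates in (("disease", cfg.disease_rates),
                            ("polymorphism", cfg.polymorphism_rates)):
        counts = simulate_counts(cfg.region_sizes, rates, rng)
        for region, count in counts.items():
            for _ in range(count):
                wt, mut = rng.choice(len(_AA_CYCLE), size=2, replace=False)
                wt, mut = _AA_CYCLE[wt], _AA_CYCLE[mut]
                pos = int(rng.integers(1, 501))
                idx += 1
                rows.append({
                    "gene": f"G{idx}",
                    "accession": f"SIM{idx:05d}",
                    "change": f"p.{ONE_TO_THREE[wt].capitalize()}{pos}"
                              f"{ONE_TO_THREE[mut].capitalize()}",
                    "category": category,
                    "region": region,
                })
    return pd.DataFrame(
        rows, columns=["gene", "accession", "change", "category", "region"])


def savs_for_complex(
    complex: Complex,
    config: SimulationConfig | None = None,
    rate: float = 0.35,
) -> pd.DataFrame:
    """Variant table aligned to an actual structure: each chain gets a
    pseudo-accession ``TOY_<chain>``, variant positions are residue
    numbers, wild types match the structure sequence and mutants are
    drawn uniformly from the other 19 residues.  Roughly ``rate`` of
    residues receive a variant; categories are split evenly.

    The output round-trips through :func:`intersav.variants.read_sav_table`
    (``plain_tsv``) and maps cleanly with offset 0.
    """
    cfg = config or SimulationConfig()
    rng = cfg.substreams()[1]
    rows = []
    idx = 0
    for cid, residues in complex.chains.items():
        for res in residues:
            if rng.random() >= rate:
                continue
            others = [a for a in _AA_CYCLE if a != res.aa_type]
            mut = others[int(rng.integers(0, len(others)))]
            idx += 1
            rows.append({
                "gene": f"TOYG{cid}",
                "accession": f"TOY_{cid}",
                "change": f"p.{ONE_TO_THREE[res.aa_type].capitalize()}"
                          f"{res.seq_number}{ONE_TO_THREE[mut].capitalize()}",
                "category": "disease" if rng.random() < 0.5 else "polymorphism",
            })
    return pd.DataFrame(rows, columns=["gene", "accession", "change", "category"])


def observed_counts(savs: pd.DataFrame, category: str) -> dict[str, int]:
    """Ground-truth per-region variant counts of a simulated table."""
    sub = savs[savs["category"] == category]
    return sub.groupby("region").size().to_dict()


# ---------------------------------------------------------------------------
# energies

def _mixture_params(p1: float, p2: float) -> tuple[float, float]:
    """Tail weight and exponential scale matching the two exceedances.

    The baseline component lives on [0, 1), so P(>=1) equals the tail
    weight w = p1 and P(>=2) = w * exp(-1/tau) fixes tau.
    """
    if not (0 < p2 < p1 < 1):
        raise ConfigError(f"infeasible exceedance targets ({p1}, {p2})")
    tau = 1.0 / math.log(p1 / p2)
    return p1, tau


def simulate_ddg(
    regions: list[str],
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Alanine-scan energies (and correlated variant energies) for a
    list of region labels.

    Columns: region, ddg_wt, ddg_mut.  ddg_wt follows the calibrated
    mixture of the residue's region; ddg_mut = slope * ddg_wt + noise.
    """
    cfg = config or SimulationConfig()
    rng = cfg.substreams()[2]
    n = len(regions)
    regions_arr = np.asarray(regions)
    ddg_wt = np.empty(n)
    for region in np.unique(regions_arr):
        if region not in cfg.ddg_exceedance:
            raise ConfigError(f"no ddG exceedance targets for region {region!r}")
        w, tau = _mixture_params(*cfg.ddg_exceedance[region])
        mask = regions_arr == region
        k = int(mask.sum())
        in_tail = rng.random(k) < w
        vals = np.abs(rng.normal(0.0, cfg.ddg_baseline_sd, size=k))
        # rejection: keep the baseline strictly below 1 kcal/mol
        while (vals >= 1.0).any():
            redo = vals >= 1.0
            vals[redo] = np.abs(rng.normal(0.0, cfg.ddg_baseline_sd, size=int(redo.sum())))
        vals[in_tail] = 1.0 + rng.exponential(tau, size=int(in_tail.sum()))
        ddg_wt[mask] = vals
    ddg_mut = cfg.ddg_mut_slope * ddg_wt + rng.normal(
        0.0, cfg.ddg_mut_noise_sd, size=n)
    return pd.DataFrame({"region": regions_arr, "ddg_wt": ddg_wt, "ddg_mut": ddg_mut})


def ddg_table_for_complex(
    complex: Complex,
    region_by_key: dict,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Per-residue energy table (chain, resnum, icode, ddg_wt, mut_aa,
    ddg_mut) for the interface residues of a toy complex, in the format
    :func:`intersav.energetics.read_ddg_table` reads."""
    cfg = config or SimulationConfig()
    keys = [k for k, region in region_by_key.items() if region in ("core", "rim")]
    regions = [region_by_key[k] for k in keys]
    if not keys:
        return pd.DataFrame(columns=["chain", "resnum", "icode", "ddg_wt", "mut_aa", "ddg_mut"])
    energies = simulate_ddg(regions, cfg)
    rng = cfg.substreams()[3]
    muts = [_AA_CYCLE[int(i)] for i in rng.integers(0, 20, size=len(keys))]
    return pd.DataFrame({
        "chain": [k[0] for k in keys],
        "resnum": [k[1] for k in keys],
        "icode": [k[2] for k in keys],
        "ddg_wt": energies["ddg_wt"].to_numpy(),
        "mut_aa": muts,
        "ddg_mut": energies["ddg_mut"].to_numpy(),
    })
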