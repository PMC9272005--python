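"""Seeded synthetic-data generators for end-to-end pipeline testing.

Real candidate protein sequences are not bundled with the package, so
the sequence stages are exercised on generated families: reference GLYI
domains embedded in random flanking sequence, with ground-truth activity,
metal type, architecture and planted site mutations recorded in a truth
table.  Kinetics and Ct generators reproduce the study's assay designs
(the 0.025-1 mM hemithioacetal series, the Dixon S x I grid, the
9-gene x 3-condition x 2-tissue x 3-replicate expression layout) around
the reported ground-truth parameters.  Every generator is a pure function
of its seed.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import AMINO_ACIDS, DomainSpan, ProteinRecord
from .classify import ReferenceProfile, builtin_profiles
from .kinetics import KineticParams, KineticsDataset, competitive_rate, mm_rate

__all__ = [
    "DWM_PARAMS",
    "MM_DESIGN_S",
    "DIXON_DESIGN_S",
    "DIXON_DESIGN_I",
    "ZN_DOSES",
    "ACTIVE_GENES",
    "make_protein_family",
    "make_kinetics",
    "make_ct_table",
    "table_fixtures",
    "proteins_to_fasta",
]

#: Ground-truth kinetic parameters of the mitochondrial GLYI activity:
#: Vmax 0.519 umol min^-1 mg^-1, Km 92 uM, GSH Ki 6.5 mM.
DWM_PARAMS = KineticParams(vmax=0.519, km=0.092, ki=6.5)

#: 12-point substrate series spanning the assayed 0.025-1 mM HA range.
MM_DESIGN_S = (0.025, 0.05, 0.075, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.65,
               0.8, 1.0)

#: Dixon design: substrate series at fixed free-GSH inhibitor levels.
DIXON_DESIGN_S = (0.1, 0.25, 0.5, 1.0)
DIXON_DESIGN_I = (0.2, 1.0, 5.0, 10.0, 15.0)

#: Zn2+ activation dose range, mM.
ZN_DOSES = (0.125, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5)

#: The nine genes encoding putatively active isoforms, used as the default
#: expression panel.
ACTIVE_GENES = ("TdGLYI-1B-4", "TdGLYI-2A-1", "TdGLYI-2B-1", "TdGLYI-5A-1",
                "TdGLYI-5A-2", "TdGLYI-5B-1", "TdGLYI-6A-2", "TdGLYI-7A-1",
                "TdGLYI-7B-1")

_AA = np.array(list(AMINO_ACIDS))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def _mutate(domain: str, positions: Sequence[int]) -> str:
    chars = list(domain)
    for pos in positions:
        chars[pos - 1] = "A"       # no checked site expects alanine
    return "".join(chars)


def make_protein_family(n: int = 54,
                        fraction_active: float = 28 / 54,
                        ni_fraction: float = 23 / 28,
                        two_domain_fraction: float = 17 / 28,
                        seed: int = 0,
                        profiles: Mapping[str, ReferenceProfile] | None = None,
                        ) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate a GLYI-like protein family with known ground truth.

    Exactly ``round(n * fraction_active)`` proteins carry an intact
    reference domain (Ni-type or Zn-type in the given mix, with the study's
    one-/two-domain architecture mix); the rest are inactivated either by
    1-7 planted conserved-site mutations or by domain truncation below the
    length filter.  The defaults mirror the curated family: 54 candidates,
    28 active (23 Ni / 5 Zn), 17 of the active two-domain.

    Returns the protein records (sequences, domain spans) and a truth
    table with one row per protein.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= fraction_active <= 1:
        raise ValueError("fraction_active must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    profiles = profiles or builtin_profiles()
    by_metal = {p.metal_type: p for p in profiles.values()}

    n_active = round(n * fraction_active)
    n_ni = round(n_active * ni_fraction)
    n_two = round(n_active * two_domain_fraction)
    labels = []
    for k in range(n_active):
        labels.append(("active", "Ni" if k < n_ni else "Zn", k < n_two))
    n_inactive = n - n_active
    n_trunc = n_inactive // 3          # a third of the duds are fragments
    for k in range(n_inactive):
        labels.append(("truncated" if k < n_trunc else "mutated", None, False))
    labels = [labels[i] for i in rng.permutation(len(labels))]

    records: list[ProteinRecord] = []
    truth_rows = []
    for idx, (kind, metal, two_domain) in enumerate(labels):
        profile = by_metal[metal] if metal else by_metal[
            rng.choice(["Ni", "Zn"])
        ]
        domain = profile.domain_sequence
        n_mut = 0
        mutated_sites: list[int] = []
        if kind == "mutated":
            n_mut = int(rng.integers(1, 8))
            site_positions = [pos for _k, pos, _r in profile.all_sites]
            mutated_sites = sorted(
                rng.choice(site_positions, size=n_mut, replace=False).tolist()
            )
            domain = _mutate(domain, mutated_sites)
        elif kind == "truncated":
            cut = int(rng.integers(60, 100))
            domain = domain[:cut]

        nflank = _random_seq(rng, int(rng.integers(5, 41)))
        cflank = _random_seq(rng, int(rng.integers(5, 41)))
        start = len(nflank) + 1
        spans = [DomainSpan(length=len(domain), start=start,
                            end=start + len(domain) - 1)]
        seq = nflank + domain
        if two_domain:
            linker = _random_seq(rng, int(rng.integers(5, 21)))
            # degenerate C-terminal copy: second metal residue knocked out
            second = _mutate(profile.domain_sequence,
                             [profile.metal_sites[1][0]])
            s2 = len(seq) + len(linker) + 1
            spans.append(DomainSpan(length=len(second), start=s2,
                                    end=s2 + len(second) - 1))
            seq = seq + linker + second
        seq = seq + cflank

        pid = f"synGLYI-{idx + 1:03d}"
        records.append(ProteinRecord(protein_id=pid, length=len(seq),
                                     sequence=seq, domains=spans))
        truth_rows.append({
            "protein_id": pid,
            "active": kind == "active",
            "metal": metal or "none",
            "architecture": "two-domain" if two_domain else "one-domain",
            "kind": kind,
            "n_mutations": n_mut,
            "mutated_sites": ",".join(map(str, mutated_sites)),
            "profile": profile.name,
            "seed": seed,
        })
    return records, pd.DataFrame(truth_rows)


def proteins_to_fasta(records: Sequence[ProteinRecord], width: int = 60) -> str:
    """Deterministic FASTA serialization (IDs = protein_id, wrapped)."""
    chunks = []
    for rec in records:
        if rec.sequence is None:
            raise ValueError(f"{rec.protein_id}: no sequence to write")
        chunks.append(f">{rec.protein_id}")
        chunks.extend(rec.sequence[i:i + width]
                      for i in range(0, len(rec.sequence), width))
    return "\n".join(chunks) + "\n"


def make_kinetics(params: KineticParams = DWM_PARAMS,
                  s_design: Sequence[float] = MM_DESIGN_S,
                  i_design: Sequence[float] | None = None,
                  noise_sigma: float = 0.0,
                  replicates: int = 1,
                  seed: int = 0) -> tuple[KineticsDataset, pd.DataFrame]:
    """Rates on an S (x I) design with Gaussian noise scaled to Vmax.

    With an inhibitor design the full S x I grid is generated from the
    competitive model; otherwise plain Michaelis-Menten rates.  Noise is
    N(0, noise_sigma * Vmax), truncated at zero.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    if not s_design:
        raise ValueError("empty substrate design")
    rng = np.random.default_rng(seed)
    s_grid, i_grid = [], []
    for s in s_design:
        for i in (i_design if i_design else (0.0,)):
            for _ in range(replicates):
                s_grid.append(s)
                i_grid.append(i)
    s_arr = np.array(s_grid)
    i_arr = np.array(i_grid)
    if i_design:
        v = np.asarray(competitive_rate(params, s_arr, i_arr))
    else:
        v = np.asarray(mm_rate(params, s_arr))
    if noise_sigma > 0:
        v = v + rng.normal(0.0, noise_sigma * params.vmax, size=v.shape)
    v = np.clip(v, 0.0, None)
    truth = pd.DataFrame([{
        "vmax": params.vmax, "km": params.km, "ki": params.ki,
        "noise_sigma": noise_sigma, "seed": seed,
    }])
    return KineticsDataset(s=s_arr, v=v, i=i_arr), truth


def make_ct_table(effects: Mapping[tuple[str, str], float] | None = None,
                  genes: Sequence[str] = ACTIVE_GENES,
                  conditions: Sequence[str] = ("control", "NaCl", "mannitol"),
                  tissues: Sequence[str] = ("shoot", "root"),
                  ref_genes: Sequence[str] = ("CDC", "RLI"),
                  n_bio: int = 3,
                  n_tech: int = 3,
                  ct_sd: float = 0.1,
                  seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic Ct table with planted log2 expression effects.

    ``effects`` maps (gene, condition) to a planted log2 fold change
    relative to the first (calibrator) condition in the same tissue; a
    positive effect lowers the target Ct by that many cycles.  Reference
    genes always carry zero effect (planting one raises an error).
    Baselines are drawn per gene x tissue in the realistic 18-30 cycle
    window; technical-replicate noise is N(0, ct_sd).
    """
    effects = dict(effects or {})
    for (gene, _cond) in effects:
        if gene in ref_genes:
            raise ValueError(f"effect planted on reference gene {gene!r}")
    rng = np.random.default_rng(seed)
    all_genes = list(genes) + list(ref_genes)
    baseline = {
        (g, t): rng.uniform(18.0, 30.0) for g in all_genes for t in tissues
    }
    rows = []
    truth_rows = []
    for tissue in tissues:
        for cond in conditions:
            for b in range(1, n_bio + 1):
                sample = f"{cond}_{tissue}_b{b}"
                shift = rng.normal(0.0, 0.3)   # per-sample plate/loading shift
                for gene in all_genes:
                    effect = effects.get((gene, cond), 0.0)
                    if gene in ref_genes:
                        effect = 0.0
                    true_ct = baseline[(gene, tissue)] - effect + shift
                    for r in range(1, n_tech + 1):
                        ct = true_ct + (rng.normal(0.0, ct_sd) if ct_sd else 0)
                        rows.append({"sample": sample, "condition": cond,
                                     "tissue": tissue, "gene": gene,
                                     "rep": r, "ct": ct})
    for (gene, cond), eff in effects.items():
        for tissue in tissues:
            truth_rows.append({"gene": gene, "condition": cond,
                               "tissue": tissue, "log2_effect": eff,
                               "seed": seed})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def table_fixtures(outdir=None) -> dict[str, pd.DataFrame]:
    """The three printed family tables as machine-readable frames.

    table1: the full gene/transcript catalog (60 transcript rows);
    table2: per-protein conserved-site calls (54 post-filter rows);
    table3: per-variant localization predictions (28 active variants).
    With ``outdir``, each is also written as ``<outdir>/<name>.tsv``.
    """
    names = {
        "table1": "table1_catalog.tsv",
        "table2": "table2_sites.tsv",
        "table3": "table3_localization.tsv",
    }
    out = {}
    for key, fname in names.items():
        ref = resources.files("glyi.data") / fname
        with ref.open() as fh:
            out[key] = pd.read_csv(fh, sep="\t", dtype=str)
    for key in ("table1",):
        for col in ("cds_bp", "exons", "protein_aa"):
            out[key][col] = out[key][col].astype(int)
    if outdir is not None:
        import pathlib
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key, fname in names.items():
            out[key].to_csv(outdir / fname, sep="\t", index=False)
    return out


def fixture_path(name: str):
    """Filesystem path of a packaged fixture table (table1|table2|table3)."""
    fname = {
        "table1": "table1_catalog.tsv",
        "table2": "table2_sites.tsv",
        "table3": "table3_localization.tsv",
    }[name]
    return resources.files("glyi.data") / fname
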