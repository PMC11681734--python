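"""Synthetic study generator with planted, known ground truth.

Emulates the full ex vivo design: whole blood from 4-5 individuals of 4
resilient species (mouse, rat, rhesus, baboon) and 6 sensitive species
(rabbit, pig, cow, sheep, chimpanzee, human), incubated with 0, 10, 100 or
1000 ng/mL LPS for 2, 6 or 24 h.  Expression is generated in the human
ortholog space on the log2 scale — gene-level mean mu_g ~ Uniform(2, 10)
log2 TPM, a per-(gene, species) random shift (species genuinely differ in
baseline expression beyond their group, which is what makes species-level
blocking informative), an individual-level random intercept shared across an
individual's samples (making the paired design informative), and i.i.d.
log-normal noise — then pushed down into each species' own gene space by inverting sampled
m:n orthology topologies, so the translation step is exercised for real.

Planted structure (all sets disjoint, sizes and effects configurable):

* baseline group effects: a +/- shift of one group's unstimulated mean;
* LPS response effects: a log2 induction shared by all species, scaled by a
  dose-saturation factor (10: 0.8, 100: 0.9, 1000: 1.0 — dose escalation has
  deliberately little extra effect) and a time profile peaking at 6 h;
* group response differences: responders whose induction differs between the
  groups by a planted delta (mostly stronger in the resilient group).

The proteome generator plants proteins for each of the three discrimination
tiers: a group shift detectable by ANOVA; a large fold change with
missingness that denies the ANOVA tier a p-value; and strict one-group
presence in at least three species.

Identical seeds produce byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from xlps.data_io import (
    RESILIENT_SPECIES,
    SENSITIVE_SPECIES,
    ExpressionMatrix,
    ProteinTable,
    SampleSheet,
)
from xlps.orthologs import OrthologMap, merge_species, translate

DOSE_SATURATION = {10.0: 0.8, 100.0: 0.9, 1000.0: 1.0}
TIME_PROFILE = {2.0: 0.7, 6.0: 1.0, 24.0: 0.5}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study; the seed fully determines every output."""

    n_resilient_species: int = 4
    n_sensitive_species: int = 6
    individuals_per_species: int = 5
    n_human_orthologs: int = 2000
    frac_baseline_de: float = 0.10
    baseline_effect_log2: float = 1.5
    baseline_sensitive_up_frac: float = 0.5
    frac_response_de: float = 0.10
    response_effect_log2: float = 2.0
    frac_group_response_diff: float = 0.05
    group_diff_effect_log2: float = 1.5
    group_diff_resilient_up_frac: float = 0.8
    base_response_of_diff_genes_log2: float = 0.5
    dose_saturation: Mapping[float, float] = field(default_factory=lambda: dict(DOSE_SATURATION))
    time_profile: Mapping[float, float] = field(default_factory=lambda: dict(TIME_PROFILE))
    noise_sd_log2: float = 0.5
    individual_sd_log2: float = 0.3
    species_sd_log2: float = 0.3
    ortholog_topology_weights: Mapping[str, float] = field(
        default_factory=lambda: {"1:1": 0.80, "2:1": 0.06, "1:2": 0.06, "2:3": 0.03, "missing": 0.05}
    )
    doses: tuple[float, ...] = (0.0, 10.0, 100.0, 1000.0)
    times: tuple[float, ...] = (2.0, 6.0, 24.0)
    pseudocount: float = 1.0
    # proteome
    n_proteins: int = 500
    n_tier_anova: int = 15
    n_tier_foldchange: int = 15
    n_tier_presence: int = 15
    protein_noise_sd: float = 1.0
    anova_shift_log2: float = 3.0
    foldchange_shift_log2: float = 5.5
    background_detect_prob: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_baseline_de, self.frac_response_de, self.frac_group_response_diff)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("planted fractions must lie in [0, 1]")
        if sum(fracs) > 1:
            raise ValueError("planted fractions exceed 1 in total; sets must be disjoint")
        topo = set(self.ortholog_topology_weights)
        if not topo <= {"1:1", "2:1", "1:2", "2:3", "missing"}:
            raise ValueError(f"unknown topology key(s): {sorted(topo - {'1:1', '2:1', '1:2', '2:3', 'missing'})}")
        planted = self.n_tier_anova + self.n_tier_foldchange + self.n_tier_presence
        if planted > self.n_proteins:
            raise ValueError("planted proteins exceed n_proteins")

    def response_factor(self, dose: float, time: float) -> float:
        """Planted dose x time multiplier for response effects (0 for dose 0)."""
        if dose == 0:
            return 0.0
        return float(self.dose_saturation.get(dose, 1.0) * self.time_profile.get(time, 1.0))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("doses", "times"):
            if key in raw:
                raw[key] = tuple(float(x) for x in raw[key])
        for key in ("dose_saturation", "time_profile"):
            if key in raw:
                raw[key] = {float(k): float(v) for k, v in raw[key].items()}
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted effects, keyed by human ortholog / protein ID.

    baseline_de_genes maps gene -> +1 (higher in sensitive) or -1;
    response_genes maps gene -> planted base log2 induction (all species);
    group_response_diff_genes maps gene -> resilient-minus-sensitive response
    delta; tiered_proteins maps protein -> planted tier name.
    """

    baseline_de_genes: dict[str, int] = field(default_factory=dict)
    response_genes: dict[str, float] = field(default_factory=dict)
    group_response_diff_genes: dict[str, float] = field(default_factory=dict)
    tiered_proteins: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("baseline_de", g, str(v)) for g, v in sorted(self.baseline_de_genes.items())]
        rows += [("response", g, format(v, ".10g")) for g, v in sorted(self.response_genes.items())]
        rows += [("group_response_diff", g, format(v, ".10g"))
                 for g, v in sorted(self.group_response_diff_genes.items())]
        rows += [("protein_tier", p, t) for p, t in sorted(self.tiered_proteins.items())]
        return pd.DataFrame(rows, columns=["kind", "feature_id", "value"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _species_names(cfg: SimulationConfig) -> tuple[list[str], list[str]]:
    res = list(RESILIENT_SPECIES[: cfg.n_resilient_species])
    res += [f"resilient{i + 1}" for i in range(len(res), cfg.n_resilient_species)]
    sens = list(SENSITIVE_SPECIES[: cfg.n_sensitive_species])
    sens += [f"sensitive{i + 1}" for i in range(len(sens), cfg.n_sensitive_species)]
    return res, sens


def _build_sheet(cfg: SimulationConfig) -> SampleSheet:
    res, sens = _species_names(cfg)
    rows = []
    for sp in res + sens:
        group = "resilient" if sp in res else "sensitive"
        for i in range(1, cfg.individuals_per_species + 1):
            ind = f"{sp}_i{i}"
            for t in cfg.times:
                for d in cfg.doses:
                    rows.append({
                        "sample_id": f"{sp}_i{i}_d{d:g}_t{t:g}", "species": sp, "group": group,
                        "individual": ind, "dose": d, "time": t,
                    })
    sheet = SampleSheet(pd.DataFrame(rows))
    sheet.validate(require_pairing=0.0 in cfg.doses)
    return sheet


def _global_components(cfg: SimulationConfig, rng: np.random.Generator,
                       planted: np.ndarray) -> list[tuple[int, list[int]]]:
    """Sample the study-wide orthology component structure.

    Each human gene is assigned once, for the whole study, to an m:n
    component class — 1:1, 2:1 (two species paralogs for one human gene),
    1:2 or 2:3 (one/two species genes shared by a human paralog pair/triple).
    The "missing" weight is *not* consumed here: annotation incompleteness is
    a per-species property and is applied as per-(component, species) dropout
    at emission time.  Planted genes are restricted to n = 1 classes so their
    effects survive the sum/n translation undiluted; merged components
    consume runs of adjacent non-planted genes.

    Returns components as (m species genes, human gene indices).
    """
    n = cfg.n_human_orthologs
    w = cfg.ortholog_topology_weights
    topo_names = ["1:1", "2:1", "1:2", "2:3"]
    probs = np.array([w.get(t, 0.0) for t in topo_names], dtype=float)
    probs /= probs.sum()
    n1_probs = probs[:2] / probs[:2].sum()

    components: list[tuple[int, list[int]]] = []
    g = 0
    while g < n:
        if planted[g]:
            topo = topo_names[rng.choice(2, p=n1_probs)]
        else:
            topo = topo_names[rng.choice(4, p=probs)]
        if topo == "1:1":
            components.append((1, [g]))
            g += 1
        elif topo == "2:1":
            components.append((2, [g]))
            g += 1
        else:
            need = 2 if topo == "1:2" else 3
            block = [g]
            h = g + 1
            while h < n and len(block) < need and not planted[h]:
                block.append(h)
                h += 1
            if len(block) < need:  # not enough adjacent non-planted genes
                components.append((1, [g]))
                g += 1
            else:
                components.append((1 if topo == "1:2" else 2, block))
                g = h
    return components


@dataclass
class SimulatedTranscriptome:
    """In-memory result of :func:`simulate_transcriptome`."""

    config: SimulationConfig
    sheet: SampleSheet
    human_universe: list[str]
    species_matrices: dict[str, ExpressionMatrix]  # species gene space, TPM
    ortholog_maps: dict[str, OrthologMap]
    truth: GroundTruth

    def to_human_space(self) -> ExpressionMatrix:
        """Translate every species and merge into one human-space TPM matrix."""
        mats = [translate(self.species_matrices[sp], self.ortholog_maps[sp], self.human_universe)
                for sp in sorted(self.species_matrices)]
        return merge_species(mats, self.sheet)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.sheet.frame.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
        (out / "human_universe.txt").write_text("\n".join(self.human_universe) + "\n")
        for sp, mat in sorted(self.species_matrices.items()):
            df = pd.DataFrame(mat.values, index=mat.gene_ids, columns=mat.sample_ids)
            df.index.name = "gene_id"
            df.to_csv(out / f"{sp}_expression.tsv", sep="\t", float_format="%.10g")
            self.ortholog_maps[sp].write(out / f"{sp}_orthologs.tsv")
        self.truth.write(out / "ground_truth.tsv")


def simulate_transcriptome(cfg: SimulationConfig | None = None,
                           out_dir: str | Path | None = None) -> SimulatedTranscriptome:
    """Generate the full multi-species stimulation study with known truth."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_human_orthologs
    universe = [f"HG{i:05d}" for i in range(n)]
    sheet = _build_sheet(cfg)
    res_names, sens_names = _species_names(cfg)

    mu = rng.uniform(2.0, 10.0, size=n)

    order = rng.permutation(n)
    n_base = int(round(cfg.frac_baseline_de * n))
    n_resp = int(round(cfg.frac_response_de * n))
    n_diff = int(round(cfg.frac_group_response_diff * n))
    base_idx = order[:n_base]
    resp_idx = order[n_base:n_base + n_resp]
    diff_idx = order[n_base + n_resp:n_base + n_resp + n_diff]

    base_sign = np.where(rng.random(n_base) < cfg.baseline_sensitive_up_frac, 1, -1)
    diff_sign = np.where(rng.random(n_diff) < cfg.group_diff_resilient_up_frac, 1, -1)

    truth = GroundTruth(
        baseline_de_genes={universe[i]: int(s) for i, s in zip(base_idx, base_sign)},
        response_genes={universe[i]: float(cfg.response_effect_log2) for i in resp_idx},
        group_response_diff_genes={universe[i]: float(s * cfg.group_diff_effect_log2)
                                   for i, s in zip(diff_idx, diff_sign)},
    )

    baseline_shift = {"sensitive": np.zeros(n), "resilient": np.zeros(n)}
    baseline_shift["sensitive"][base_idx[base_sign > 0]] = cfg.baseline_effect_log2
    baseline_shift["resilient"][base_idx[base_sign < 0]] = cfg.baseline_effect_log2

    # per-group planted response magnitude per gene
    resp_gene = {"sensitive": np.zeros(n), "resilient": np.zeros(n)}
    for grp in ("sensitive", "resilient"):
        resp_gene[grp][resp_idx] = cfg.response_effect_log2
        resp_gene[grp][diff_idx] = cfg.base_response_of_diff_genes_log2
    resp_gene["resilient"][diff_idx[diff_sign > 0]] += cfg.group_diff_effect_log2
    resp_gene["sensitive"][diff_idx[diff_sign < 0]] += cfg.group_diff_effect_log2

    planted = np.zeros(n, dtype=bool)
    planted[np.concatenate([base_idx, resp_idx, diff_idx]).astype(int)] = True

    components = _global_components(cfg, rng, planted)
    p_missing = float(cfg.ortholog_topology_weights.get("missing", 0.0))

    species_matrices: dict[str, ExpressionMatrix] = {}
    ortholog_maps: dict[str, OrthologMap] = {}
    frame = sheet.frame
    for sp in res_names + sens_names:
        group = "resilient" if sp in res_names else "sensitive"
        meta = frame[frame["species"] == sp].reset_index(drop=True)
        individuals = sorted(meta["individual"].unique())
        intercept = dict(zip(individuals, rng.normal(0.0, cfg.individual_sd_log2, len(individuals))))

        factors = np.array([cfg.response_factor(d, t) for d, t in zip(meta["dose"], meta["time"])])
        species_shift = rng.normal(0.0, cfg.species_sd_log2, size=n)
        x = (mu[:, None] + species_shift[:, None] + baseline_shift[group][:, None]
             + np.outer(resp_gene[group], factors)
             + np.array([intercept[i] for i in meta["individual"]])[None, :]
             + rng.normal(0.0, cfg.noise_sd_log2, size=(n, len(meta))))
        tpm_human = np.maximum(np.exp2(x) - cfg.pseudocount, 0.0)

        # per-species annotation dropout: whole components go unannotated;
        # the reference species (human) maps to itself completely
        dropout = np.zeros(len(components), dtype=bool)
        if sp != "human":
            dropout = rng.random(len(components)) < p_missing

        pairs: list[tuple[str, str]] = []
        sgene_ids: list[str] = []
        rows: list[np.ndarray] = []
        counter = 0
        for ci, (m, hidx) in enumerate(components):
            if dropout[ci]:
                continue
            sgenes = [f"{sp}_G{counter + j:05d}" for j in range(m)]
            counter += m
            pairs.extend((sg, universe[h]) for sg in sgenes for h in hidx)
            total = tpm_human[hidx].sum(axis=0)
            shares = np.array([1.0]) if m == 1 else rng.dirichlet(np.ones(m))
            for sg, share in zip(sgenes, shares):
                sgene_ids.append(sg)
                rows.append(share * total)
        ortholog_maps[sp] = OrthologMap.from_pairs(sp, pairs)
        values = np.vstack(rows) if rows else np.zeros((0, len(meta)))
        species_matrices[sp] = ExpressionMatrix(
            sgene_ids, list(meta["sample_id"]), values,
            np.zeros_like(values, dtype=bool), scale="tpm",
        )

    sim = SimulatedTranscriptome(cfg, sheet, universe, species_matrices, ortholog_maps, truth)
    if out_dir is not None:
        sim.write(out_dir)
    return sim


def simulate_proteome(cfg: SimulationConfig | None = None,
                      out_dir: str | Path | None = None) -> tuple[ProteinTable, GroundTruth]:
    """Generate a plasma LFQ table with proteins planted for each capture tier."""
    cfg = cfg or SimulationConfig()
    # independent stream: proteome outputs must not depend on transcriptome size
    rng = np.random.default_rng((cfg.seed, 1))
    res_names, sens_names = _species_names(cfg)
    species = res_names + sens_names
    groups = {sp: ("resilient" if sp in res_names else "sensitive") for sp in species}
    sens_cols = np.array([groups[sp] == "sensitive" for sp in species])
    n_sp = len(species)

    proteins = [f"P{i:04d}" for i in range(cfg.n_proteins)]
    base = rng.uniform(18.0, 30.0, size=cfg.n_proteins)
    lfq = base[:, None] + rng.normal(0.0, cfg.protein_noise_sd, size=(cfg.n_proteins, n_sp))
    detected = rng.random((cfg.n_proteins, n_sp)) < cfg.background_detect_prob

    order = rng.permutation(cfg.n_proteins)
    idx_anova = order[:cfg.n_tier_anova]
    idx_fc = order[cfg.n_tier_anova:cfg.n_tier_anova + cfg.n_tier_foldchange]
    idx_pres = order[cfg.n_tier_anova + cfg.n_tier_foldchange:
                     cfg.n_tier_anova + cfg.n_tier_foldchange + cfg.n_tier_presence]

    truth = GroundTruth()
    for j, i in enumerate(idx_anova):
        up = "sensitive" if j % 2 == 0 else "resilient"
        shift_cols = sens_cols if up == "sensitive" else ~sens_cols
        lfq[i, shift_cols] += cfg.anova_shift_log2
        detected[i, :] = True  # full detection: ANOVA tier must get its p-value
        truth.tiered_proteins[proteins[i]] = "anova"

    for j, i in enumerate(idx_fc):
        up = "sensitive" if j % 2 == 0 else "resilient"
        up_cols = np.nonzero(sens_cols if up == "sensitive" else ~sens_cols)[0]
        lo_cols = np.nonzero(~sens_cols if up == "sensitive" else sens_cols)[0]
        detected[i, :] = False
        keep_up = rng.choice(up_cols, size=min(4, len(up_cols)), replace=False)
        keep_lo = rng.choice(lo_cols, size=1, replace=False)  # one value: no ANOVA p
        detected[i, keep_up] = True
        detected[i, keep_lo] = True
        lfq[i, keep_up] += cfg.foldchange_shift_log2
        truth.tiered_proteins[proteins[i]] = "foldchange"

    for j, i in enumerate(idx_pres):
        grp_cols = np.nonzero(sens_cols if j % 2 == 0 else ~sens_cols)[0]
        detected[i, :] = False
        keep = rng.choice(grp_cols, size=min(4, len(grp_cols)), replace=False)
        detected[i, keep] = True
        truth.tiered_proteins[proteins[i]] = "presence"

    table = ProteinTable(proteins, species, lfq, detected, groups=groups)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(np.where(detected, lfq, np.nan), index=proteins, columns=species)
        df.index.name = "protein_id"
        df.to_csv(out / "protein_lfq.tsv", sep="\t", float_format="%.10g", na_rep="NA")
        pd.DataFrame({"species": species, "group": [groups[s] for s in species]}).to_csv(
            out / "protein_groups.tsv", sep="\t", index=False)
        truth.write(out / "protein_ground_truth.tsv")
    return table, truth
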