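"""End-to-end screening pipeline.

Given compound descriptors and either measured or simulated screening
observations, :func:`run_full_screen` emits, per drug:

* a solubility-parameter table (both group-contribution methods),
* a screening table (Greenhalgh differences, Flory-Huggins chi under both
  methods, Bagley distances),
* free-energy phase-diagram profiles and their summaries,
* the miscibility class grid,
* polymer rankings per screening method with position/identity concordance
  against the spray-dryer reference,
* PCA score/loading/variance tables over the class grid and over the
  concordance scores,

plus a manifest recording the configuration hash and seed.  Identical
configuration and seed give byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import compare, criteria, flory, io as aio, ranking
from .classify import METHOD_IDS, classify_campaign
from .constants import T_AMBIENT_K, TG_MATCH_TOL_C, TG_RESOLUTION_C
from .errors import DegenerateMatrixError, ValidationError
from .groups import compound_parameters, polymer_chain_volume
from .synthetic import CampaignSpec, make_campaign, planted_max_a_loading


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one full screening run."""

    drugs: tuple[str, ...] = aio.DRUGS
    polymers: tuple[str, ...] = aio.POLYMERS
    temperature_k: float = T_AMBIENT_K
    greenhalgh_cutoff: float = 7.0
    tg_tol_c: float = TG_MATCH_TOL_C
    tg_resolution_c: float = TG_RESOLUTION_C
    grid_points: int = 2001
    seed: int = 0
    observations: str | None = None  # path to a measured observation table
    out_dir: str = "screen_out"

    def __post_init__(self) -> None:
        if self.temperature_k <= 0:
            raise ValidationError("temperature must be positive")
        for name in ("greenhalgh_cutoff", "tg_tol_c", "tg_resolution_c"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def parameter_table(compounds, tables) -> pd.DataFrame:
    """Solubility parameters of every compound under both methods."""
    rows = []
    for abbr, comp in compounds.items():
        pf = compound_parameters(comp, tables["fedors"])
        pv = compound_parameters(comp, tables["van_krevelen"])
        rows.append(
            {
                "abbr": abbr,
                "role": comp.role,
                "delta_f": pf.delta_total,
                "delta_vk": pv.delta_total,
                "delta_d": pv.delta_d,
                "delta_p": pv.delta_p,
                "delta_h": pv.delta_h,
                "v_f": pf.molar_volume,
                "v_vk": pv.molar_volume,
            }
        )
    return pd.DataFrame(rows)


def screening_table(
    compounds, tables, drugs, polymers, env: flory.EnvironmentConstants
) -> pd.DataFrame:
    """Greenhalgh / chi / Bagley screening values for every pair."""
    params = {
        abbr: {
            m: compound_parameters(compounds[abbr], tables[m])
            for m in ("fedors", "van_krevelen")
        }
        for abbr in (*drugs, *polymers)
    }
    rows = []
    for drug in drugs:
        pf_d = params[drug]["fedors"]
        pv_d = params[drug]["van_krevelen"]
        bag_d = criteria.bagley_point(pv_d, drug)
        for poly in polymers:
            pf_p = params[poly]["fedors"]
            pv_p = params[poly]["van_krevelen"]
            diff_f, verdict_f = criteria.greenhalgh(pf_d.delta_total, pf_p.delta_total)
            diff_vk, verdict_vk = criteria.greenhalgh(pv_d.delta_total, pv_p.delta_total)
            chi_f = flory.chi_from_solubility(
                pf_d.molar_volume, pf_d.delta_total, pf_p.delta_total, env,
                drug=drug, polymer=poly, method_id="fedors",
            )
            chi_vk = flory.chi_from_solubility(
                pv_d.molar_volume, pv_d.delta_total, pv_p.delta_total, env,
                drug=drug, polymer=poly, method_id="van_krevelen",
            )
            euc = criteria.bagley_distance(bag_d, criteria.bagley_point(pv_p, poly))
            rows.append(
                {
                    "drug": drug,
                    "polymer": poly,
                    "delta_diff_f": diff_f,
                    "verdict_f": verdict_f,
                    "delta_diff_vk": diff_vk,
                    "verdict_vk": verdict_vk,
                    "chi_f": chi_f.chi,
                    "chi_vk": chi_vk.chi,
                    "euc_d": euc,
                }
            )
    return pd.DataFrame(rows)


def phase_diagram_summaries(
    compounds, tables, drugs, polymers, env: flory.EnvironmentConstants,
    grid_points: int = 2001,
) -> tuple[pd.DataFrame, dict[tuple[str, str], flory.PhaseDiagram]]:
    """Fedors-based free-energy diagrams for every pair."""
    rows = []
    diagrams: dict[tuple[str, str], flory.PhaseDiagram] = {}
    for drug in drugs:
        pf_d = compound_parameters(compounds[drug], tables["fedors"])
        for poly in polymers:
            pf_p = compound_parameters(compounds[poly], tables["fedors"])
            comp = compounds[poly]
            if comp.true_density is None:
                raise ValidationError(f"{poly}: polymer density required for lattice ratio")
            m = flory.lattice_ratio(
                polymer_chain_volume(comp.mw, comp.true_density), pf_d.molar_volume
            )
            chi = flory.chi_from_solubility(
                pf_d.molar_volume, pf_d.delta_total, pf_p.delta_total, env
            ).chi
            diag = flory.classify_profile(chi, m, n_points=grid_points)
            diagrams[(drug, poly)] = diag
            rows.append(
                {
                    "drug": drug,
                    "polymer": poly,
                    "chi": chi,
                    "m": m,
                    "phi_min": diag.phi_min,
                    "phi_critical": diag.phi_critical,
                    "spinodal_lo": diag.spinodal[0] if diag.spinodal else None,
                    "spinodal_hi": diag.spinodal[1] if len(diag.spinodal) > 1 else None,
                    "profile_class": diag.profile_class,
                }
            )
    return pd.DataFrame(rows), diagrams


def default_campaign_spec(
    compounds, drugs, polymers, seed: int
) -> CampaignSpec:
    """A plausible synthetic campaign when no measured table is supplied.

    True boundaries are derived from the Fedors chi estimates (lower chi ->
    higher miscible loading), quantized to the loading grid; method biases
    follow the qualitative field observations: quench cooling over-predicts
    miscibility, slow film casting under-predicts, the atomization device
    tracks the spray dryer.
    """
    tables = {m: aio.load_bundled_table(m) for m in ("fedors", "van_krevelen")}
    env = flory.EnvironmentConstants()
    boundary = {}
    for drug in drugs:
        pf_d = compound_parameters(compounds[drug], tables["fedors"])
        for poly in polymers:
            pf_p = compound_parameters(compounds[poly], tables["fedors"])
            chi = flory.chi_from_solubility(
                pf_d.molar_volume, pf_d.delta_total, pf_p.delta_total, env
            ).chi
            if chi < 1.0:
                b = 0.6
            elif chi < 2.0:
                b = 0.4
            else:
                b = 0.2
            boundary[(drug, poly)] = b
    return CampaignSpec(
        drugs=tuple(drugs),
        polymers=tuple(polymers),
        true_boundary=boundary,
        method_bias={"QC": 0.2, "FC_RT": -0.2, "FC_RP": 0.0, "AD": 0.0, "SD": 0.0},
        seed=seed,
    )


def rank_and_score(
    campaign_classes, class_records, drugs, polymers, screening: pd.DataFrame,
    reference_method: str = "SD",
) -> tuple[pd.DataFrame, dict[str, dict[str, tuple[float, float]]]]:
    """Experimental + theoretical rankings and concordance vs the reference.

    ``campaign_classes`` maps (drug, polymer, loading, method) -> label;
    ``class_records`` the underlying records (for Tg tie-breaks).
    """
    tg_stats: dict[tuple[str, str, float, str], tuple[float, float]] = {}
    acc: dict[tuple[str, str, float, str], list[tuple[float, float]]] = {}
    for rec in class_records:
        if len(rec.tg_events) == 1:
            key = (rec.drug, rec.polymer, rec.drug_loading, rec.method)
            acc.setdefault(key, []).append(
                (rec.tg_events[0].value, rec.tg_events[0].width)
            )
    for key, pairs in acc.items():
        tg_stats[key] = (
            sum(v for v, _ in pairs) / len(pairs),
            sum(w for _, w in pairs) / len(pairs),
        )

    methods = sorted({k[3] for k in campaign_classes})
    rankings: dict[str, dict[str, ranking.PolymerRanking]] = {}
    for method in methods:
        rankings[method] = {}
        for drug in drugs:
            outcomes = []
            for poly in polymers:
                cells = {
                    dl: campaign_classes[(drug, poly, dl, method)]
                    for (d, p, dl, m) in campaign_classes
                    if d == drug and p == poly and m == method
                }
                a_loadings = [dl for dl, lab in cells.items() if lab == "A"]
                best = max(cells.values(), key=lambda lab: ranking.CLASS_ORDER[lab])
                max_a = max(a_loadings) if a_loadings else None
                tg = width = None
                if max_a is not None and (drug, poly, max_a, method) in tg_stats:
                    tg, width = tg_stats[(drug, poly, max_a, method)]
                outcomes.append(
                    ranking.PolymerOutcome(
                        polymer=poly, best_class=best, max_loading_class_a=max_a,
                        tg_at_best=tg, tg_width_at_best=width,
                    )
                )
            rankings[method][drug] = ranking.rank_experimental(drug, method, outcomes)

    theo_bases = {
        "delta_chi_F": ("delta_diff_f", "delta_asc"),
        "delta_chi_VK": ("delta_diff_vk", "delta_asc"),
        "EUC": ("euc_d", "euclidean_asc"),
    }
    for name, (col, basis) in theo_bases.items():
        rankings[name] = {}
        for drug in drugs:
            sub = screening[screening["drug"] == drug]
            scores = dict(zip(sub["polymer"], sub[col]))
            rankings[name][drug] = ranking.rank_theoretical(drug, name, scores, basis)

    rows = []
    conc: dict[str, dict[str, tuple[float, float]]] = {}
    for method, per_drug in rankings.items():
        for drug, rank in per_drug.items():
            entry = {
                "method": method,
                "drug": drug,
                "ranking": ">".join(rank.top(3)),
            }
            if method != reference_method:
                scores = ranking.concordance(
                    rank.top(3), rankings[reference_method][drug].top(3)
                )
                entry["f1"] = ranking.ConcordanceScores.format_thirds(scores.f_position)
                entry["f2"] = ranking.ConcordanceScores.format_thirds(scores.f_identity)
                conc.setdefault(method, {})[drug] = (scores.f_position, scores.f_identity)
            else:
                entry["f1"] = entry["f2"] = ""
            rows.append(entry)
    return pd.DataFrame(rows), conc


def run_full_screen(config: PipelineConfig) -> Path:
    """Run every stage and write the report bundle; returns the output dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.polymers:
        raise ValidationError("polymer list must not be empty")
    compounds = aio.load_all_compounds()
    missing = [a for a in (*config.drugs, *config.polymers) if a not in compounds]
    if missing:
        raise ValidationError(f"unknown compounds: {missing}")
    tables = {m: aio.load_bundled_table(m) for m in ("fedors", "van_krevelen")}
    env = flory.EnvironmentConstants(temperature_k=config.temperature_k)

    params = parameter_table(
        {a: compounds[a] for a in (*config.drugs, *config.polymers)}, tables
    )
    aio.write_table(params, out / "parameters.tsv", decimals=1)
    aio.write_table(params, out / "parameters_raw.tsv", decimals=None)

    screening = screening_table(
        compounds, tables, config.drugs, config.polymers, env
    )
    aio.write_table(screening, out / "screening.tsv", decimals=1)
    aio.write_table(screening, out / "screening_raw.tsv", decimals=None)

    summaries, diagrams = phase_diagram_summaries(
        compounds, tables, config.drugs, config.polymers, env, config.grid_points
    )
    aio.write_table(summaries, out / "phase_diagrams.tsv", decimals=None)
    pd_dir = out / "phase_profiles"
    pd_dir.mkdir(exist_ok=True)
    for (drug, poly), diag in diagrams.items():
        aio.write_xy(
            diag.phi, diag.delta_g, pd_dir / f"{drug}_{poly}.tsv",
            header=("phi_drug", "dG_over_RT"),
        )

    if config.observations:
        records = aio.read_observations(config.observations)
    else:
        spec = default_campaign_spec(
            compounds, config.drugs, config.polymers, config.seed
        )
        records = make_campaign(spec, compounds).records
        aio.write_observations(records, out / "observations.tsv")
    classes = classify_campaign(
        records, compounds, tol=config.tg_tol_c, resolution=config.tg_resolution_c
    )
    aio.write_table(aio.campaign_truth_frame(classes), out / "class_grid.tsv", decimals=None)

    rank_table, conc = rank_and_score(
        classes, records, config.drugs, config.polymers, screening
    )
    aio.write_table(rank_table, out / "rankings.tsv", decimals=None)

    class_matrix = compare.encode_class_matrix(classes)
    pca_classes = compare.pca(class_matrix)
    aio.write_table(
        pca_classes.scores.reset_index(names="method"), out / "pca_class_scores.tsv",
        decimals=None,
    )
    aio.write_table(
        pca_classes.loadings.reset_index(names="variable"),
        out / "pca_class_loadings.tsv", decimals=None,
    )
    prox = compare.proximity_report(pca_classes, "SD")
    aio.write_table(prox.reset_index(names="method"), out / "pca_class_proximity.tsv",
                    decimals=None)

    conc_matrix = compare.concordance_feature_matrix(conc)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-equal f1/f2 columns are expected
            pca_conc = compare.pca(conc_matrix)
    except DegenerateMatrixError:
        # too few drugs / methods for an informative decomposition
        pca_conc = None
    if pca_conc is not None:
        aio.write_table(
            pca_conc.scores.reset_index(names="method"),
            out / "pca_concordance_scores.tsv", decimals=None,
        )

    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "pca_class_variance_ratio": [float(v) for v in pca_classes.explained_variance_ratio],
        "n_observations": len(records),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
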