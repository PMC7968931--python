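"""High-level pipeline commands wiring the modules into the study's analyses.

Every command is a plain function over library objects; the CLI module is a
thin shell around these.  All outputs are TSV/dot-bracket text with a header
line recording the package version, config hash, and seed, so identical
input + config reproduce identical bytes.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    ClassifierThresholds,
    evaluate_predictions,
    load_source_table,
    quartile_check,
)
from .config import DEFAULTS, as_bool, config_hash
from .energy import EnergyModel
from .ensemble import FoldSizeError, find_ldrs, fold
from .features import feature_record
from .multivalency import Construct, ElementRegistry, component_stats, match_sites
from .intervals import count_tags, group_by_count
from .seq import RnaSequence, read_fasta
from .stats import compare_groups, mann_whitney
from .synth import (
    CohortSpec,
    find_antisense_insertion,
    gen_clip_tracks,
    gen_cohort,
    gen_hairpin,
    gen_unstructured,
)

log = logging.getLogger("meshrna")


def _model(cfg: Dict[str, str]) -> EnergyModel:
    return EnergyModel(
        kind=cfg["energy.kind"],
        temperature=float(cfg["energy.temperature_K"]),
        min_hairpin=int(cfg["fold.min_hairpin"]),
    )


def _header(cfg: Dict[str, str]) -> str:
    return (
        f"# meshrna v{__version__} config={config_hash(cfg)} "
        f"seed={cfg['seed']} energy.kind={cfg['energy.kind']}"
    )


# ---------------------------------------------------------------------------
# fold
# ---------------------------------------------------------------------------

def cmd_fold(
    fasta: Union[str, Path],
    cfg: Dict[str, str],
    out_dir: Union[str, Path],
) -> pd.DataFrame:
    """Fold every FASTA record: dot-bracket, pair probabilities, ensemble TSV.

    Sequences over ``fold.max_length`` are reported as skipped (reason
    "length"), mirroring the length limit of ensemble analysis.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seqs = read_fasta(fasta)
    model = _model(cfg)
    max_len = int(cfg["fold.max_length"])
    tau = float(cfg["ldr.tau"])
    min_ldr = int(cfg["ldr.min_length"])
    rows = []
    db_lines = [_header(cfg)]
    bpp_lines = [_header(cfg), "# id\ti\tj\tp_ij (1-based, p > 1e-6)"]
    for seq in seqs:
        if seq.n > max_len:
            log.info("skipping %s (%d nt > %d)", seq.id, seq.n, max_len)
            rows.append(
                dict(id=seq.id, length=seq.n, status="skipped:length",
                     mfe_kcal_mol=np.nan, ensemble_diversity=np.nan,
                     ned=np.nan, n_ldrs=0)
            )
            continue
        s = fold(seq, model, max_length=max_len)
        ldrs = find_ldrs(s.unpaired, tau=tau, min_ldr_length=min_ldr)
        rows.append(
            dict(id=seq.id, length=seq.n, status="ok",
                 mfe_kcal_mol=round(s.mfe_energy, 4),
                 ensemble_diversity=round(s.ensemble_diversity, 4),
                 ned=round(s.ned, 6), n_ldrs=len(ldrs))
        )
        db_lines += [
            f">{seq.id}",
            seq.residues,
            f"{s.mfe_structure.to_dot_bracket()} ({s.mfe_energy:.2f})",
            f"{s.centroid.to_dot_bracket()} (centroid)",
        ]
        iu = np.triu_indices(seq.n, k=1)
        for i, j in zip(*iu):
            p = s.bppm[i, j]
            if p > 1e-6:
                bpp_lines.append(f"{seq.id}\t{i + 1}\t{j + 1}\t{p:.6g}")
        log.info("folded %s (%d nt): ned=%.4f ldrs=%d", seq.id, seq.n, s.ned, len(ldrs))
    table = pd.DataFrame(rows)
    (out_dir / "structures.dbn").write_text("\n".join(db_lines) + "\n")
    (out_dir / "basepair_probs.tsv").write_text("\n".join(bpp_lines) + "\n")
    _write_tsv(out_dir / "ensemble.tsv", table, cfg)
    return table


def _write_tsv(path: Path, table: pd.DataFrame, cfg: Dict[str, str]) -> None:
    buf = io.StringIO()
    buf.write(_header(cfg) + "\n")
    table.to_csv(buf, sep="\t", index=False)
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def cmd_features(
    fasta: Union[str, Path], cfg: Dict[str, str], out: Optional[Path] = None
) -> pd.DataFrame:
    overlapping = as_bool(cfg["are.overlapping"])
    rows = [
        feature_record(seq, overlapping=overlapping).__dict__
        for seq in read_fasta(fasta)
    ]
    table = pd.DataFrame(rows)
    if out is not None:
        _write_tsv(Path(out), table, cfg)
    return table


# ---------------------------------------------------------------------------
# reproduce-stats
# ---------------------------------------------------------------------------

@dataclass
class StatsReport:
    comparisons: pd.DataFrame
    accuracy: float
    n_correct: int
    n_validation: int
    quartiles: Dict[str, float]
    ned_range: Tuple[float, float]

    def to_text(self, cfg: Dict[str, str]) -> str:
        lines = [_header(cfg)]
        lines.append("# group 1 = sphere, group 2 = network; two-sided Mann-Whitney")
        buf = io.StringIO()
        self.comparisons.to_csv(buf, sep="\t", index=False)
        lines.append(buf.getvalue().rstrip("\n"))
        lines.append(
            f"validation_accuracy\t{self.n_correct}/{self.n_validation}"
            f"\t{self.accuracy:.4f}"
        )
        for k, v in self.quartiles.items():
            lines.append(f"{k}\t{v:.4f}")
        lines.append(
            f"ned_range\t{self.ned_range[0]:.4f}\t{self.ned_range[1]:.4f}"
        )
        return "\n".join(lines) + "\n"


def cmd_reproduce_stats(
    table: Union[str, Path, pd.DataFrame], cfg: Dict[str, str]
) -> StatsReport:
    """Morphology-cohort statistics from a per-RNA source-data table.

    Emits the panel of Mann-Whitney Z comparisons (length on the initial
    cohort; ARE count and GC on the initial cohort restricted to < 2000 nt;
    NED on the initial and on the validation cohort), the NED-threshold
    classifier accuracy on the validation cohort, and the quartile checks at
    the two cut-offs.
    """
    df = load_source_table(table)
    continuity = as_bool(cfg["stats.continuity"])
    t = ClassifierThresholds(
        hi=float(cfg["classifier.hi"]),
        lo=float(cfg["classifier.lo"]),
        gap_rule=cfg["classifier.gap_rule"],
    )
    initial = df[df.cohort == "initial"]
    validation = df[df.cohort == "validation"]
    panels = [
        ("length_initial", initial, "length", None),
        ("n_are_initial_lt2000", initial, "n_are", lambda d: d.length < 2000),
        ("gc_initial_lt2000", initial, "gc_frac", lambda d: d.length < 2000),
        ("ned_initial", initial, "ned", None),
    ]
    if len(validation):
        panels.append(("ned_validation", validation, "ned", None))
    rows = []
    for label, part, feature, subset in panels:
        r = compare_groups(part, feature, subset=subset, continuity=continuity)
        rows.append(
            dict(panel=label, feature=feature, n1=r.n1, n2=r.n2,
                 u1=r.u1, z=round(r.z, 4), p_normal=round(r.p_two_sided, 6),
                 p_exact=(round(r.p_exact, 6) if r.p_exact is not None else ""))
        )
    comparisons = pd.DataFrame(rows)
    eval_part = validation if len(validation) else df
    ev = evaluate_predictions(eval_part, t)
    quartiles = {
        "network_frac_above_hi": quartile_check(df, "network", t.hi, "above"),
        "sphere_frac_below_lo": quartile_check(df, "sphere", t.lo, "below"),
    }
    return StatsReport(
        comparisons=comparisons,
        accuracy=ev.accuracy,
        n_correct=ev.n_correct,
        n_validation=ev.n,
        quartiles=quartiles,
        ned_range=(float(df.ned.min()), float(df.ned.max())),
    )


# ---------------------------------------------------------------------------
# classify
# ---------------------------------------------------------------------------

def cmd_classify(
    table: Union[str, Path, pd.DataFrame], cfg: Dict[str, str]
) -> pd.DataFrame:
    from .classify import classify_ned

    df = load_source_table(table)
    t = ClassifierThresholds(
        hi=float(cfg["classifier.hi"]),
        lo=float(cfg["classifier.lo"]),
        gap_rule=cfg["classifier.gap_rule"],
    )
    out = df.copy()
    out["predicted"] = out.ned.map(lambda v: classify_ned(v, t))
    out["correct"] = out.predicted == out.observed
    return out


# ---------------------------------------------------------------------------
# clip-count
# ---------------------------------------------------------------------------

def cmd_clip_count(
    utr_bed: Union[str, Path],
    peak_beds: List[Union[str, Path]],
    cfg: Dict[str, str],
    bins=((0, 0), (1, 4), (5, float("inf"))),
) -> pd.DataFrame:
    from .intervals import read_bed

    utrs = read_bed(utr_bed)
    peak_sets = [
        read_bed(p, dataset=f"dataset{k + 1}") for k, p in enumerate(peak_beds)
    ]
    counts = count_tags(
        utrs,
        peak_sets,
        strand_mode=cfg["clip.strand_mode"],
        min_overlap=int(cfg["clip.min_overlap"]),
        union_rule=cfg["clip.union_rule"],
    )
    counts["bin"] = group_by_count(counts["union"], bins)
    return counts


# ---------------------------------------------------------------------------
# simulate-net
# ---------------------------------------------------------------------------

def cmd_simulate_net(
    pool: Dict[Construct, int],
    registry: ElementRegistry,
    seed: int,
    replicates: int = 1,
) -> pd.DataFrame:
    rows = []
    for r in range(replicates):
        res = match_sites(pool, registry, seed=seed + r)
        st = component_stats(res)
        rows.append(
            dict(replicate=r, seed=seed + r, n_molecules=st.n_molecules,
                 n_edges=len(res.edges), largest=st.largest,
                 mean_size=round(st.mean_size, 3),
                 fraction_in_largest=round(st.fraction_in_largest, 4))
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end demo
# ---------------------------------------------------------------------------

def cmd_end_to_end_demo(
    seed: int = 0, quick: bool = False, cfg: Optional[Dict[str, str]] = None
) -> Dict[str, object]:
    """Generate synthetic data, fold, classify by NED, simulate the
    dimerization network, and count synthetic CLIP tags.

    Returns a dictionary of summary numbers; deterministic given the seed.
    """
    cfg = dict(DEFAULTS) if cfg is None else dict(cfg)
    cfg["seed"] = str(seed)
    model = _model(cfg)
    n_each = 5 if quick else 12
    length = 120 if quick else 200
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=4)

    log.info("stage 1: folding %d structured + %d unstructured RNAs", n_each, n_each)
    neds, labels = [], []
    stem = (length - 4) // 2
    for k in range(n_each):
        hp = gen_hairpin(stem, 4, 1.0, seed=int(sub[0]) + k)
        un = gen_unstructured(length, 0.8, seed=int(sub[1]) + k)
        neds += [fold(hp, model).ned, fold(un, model).ned]
        labels += ["structured", "unstructured"]
    med_hp = float(np.median([v for v, l in zip(neds, labels) if l == "structured"]))
    med_un = float(np.median([v for v, l in zip(neds, labels) if l == "unstructured"]))
    cut = (med_hp + med_un) / 2
    calls = ["unstructured" if v > cut else "structured" for v in neds]
    accuracy = float(np.mean([c == l for c, l in zip(calls, labels)]))

    log.info("stage 2: dimerization-network simulation")
    reg = ElementRegistry.from_pairs([("D1a", "D1b"), ("D2", "D2")])
    n_mol = 100 if quick else 400
    two_site = {
        Construct("D1a-core-D2", ("D1a", "D2")): n_mol,
        Construct("D1b-core-D2", ("D1b", "D2")): n_mol,
    }
    one_site = {
        Construct("core-D2", ("D2",)): 2 * n_mol,
    }
    st2 = component_stats(match_sites(two_site, reg, seed=int(sub[2])))
    st1 = component_stats(match_sites(one_site, reg, seed=int(sub[2]) + 1))

    log.info("stage 3: synthetic CLIP counting")
    utrs, peak_sets, truth = gen_clip_tracks(
        n_utrs=60 if quick else 150, seed=int(sub[3])
    )
    counts = count_tags(utrs, peak_sets)
    counts["bin"] = group_by_count(
        counts["union"], ((0, 0), (1, 4), (5, float("inf")))
    )
    top = counts["bin"] == ">=5"
    precision = float(truth[top.values].mean()) if top.any() else float("nan")

    return {
        "seed": seed,
        "median_ned_structured": med_hp,
        "median_ned_unstructured": med_un,
        "ned_classifier_accuracy": accuracy,
        "two_site_fraction_in_largest": st2.fraction_in_largest,
        "one_site_largest_component": st1.largest,
        "clip_top_bin_precision": precision,
        "mw_example_z": mann_whitney([1, 2, 3], [4, 5, 6]).z,
    }


def demo_cohort_report(seed: int, cfg: Dict[str, str]) -> StatsReport:
    """Reproduce the cohort statistics panel on a synthetic two-cohort table."""
    initial = gen_cohort(CohortSpec(seed=seed), cohort="initial")
    validation = gen_cohort(
        CohortSpec(n_sphere=10, n_network=14, seed=seed + 1), cohort="validation"
    )
    return cmd_reproduce_stats(pd.concat([initial, validation]), cfg)
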