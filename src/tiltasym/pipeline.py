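"""Cohort-level orchestration: preprocess → Poincaré descriptors → statistics.

The public surface follows the Model/Results idiom: build a
:class:`TiltStudy` from subject recordings (in memory or from a directory of
CSV + YAML files), call :meth:`TiltStudy.fit`, and read the report tables off
the returned :class:`StudyResults`:

``descriptors``        one row per (subject, phase, signal) with mean, SD1,
                       SD2, GI, GI_S, PI and point counts;
``exclusions``         per-subject filter report and exclusion decision;
``group_comparison``   Mann–Whitney VVS(+) vs VVS(−) per phase/signal/measure;
``within_group``       Wilcoxon supine-vs-tilt within each arm;
``friedman_table``     S1/T1/T2 Friedman omnibus + Holm-corrected pairwise
                       Wilcoxon in the vasovagal arm;
``occurrence``         asymmetry-occurrence proportions per phase;
``occurrence_tests``   Cochran Q omnibus + Holm-corrected pairwise McNemar;
``contingency``        the pairwise 2×2 occurrence tables behind them.

Every p-value in the tables traces back to a named test variant; nothing is
filtered by significance.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .poincare import PoincareSummary, classify_asymmetry, summarize_segment
from .preprocess import censor_beats, check_exclusion, extract_segments, quotient_filter
from .signals import (
    BeatSeries,
    Group,
    PhaseAnnotation,
    read_beat_series,
    read_phase_annotation,
    write_summary_table,
)
from .stats import (
    PairedTable,
    ThreeWayPattern,
    cochran_q_with_posthoc,
    friedman_with_posthoc,
    mann_whitney,
    wilcoxon_signed_rank,
)

__all__ = ["StudyConfig", "TiltStudy", "StudyResults", "run_study", "tabulate_occurrence"]

MEASURES = ("mean", "sd1", "sd2", "gi", "gi_s", "pi")
INDEX_CRITERIA = ("gi_asym", "pi_asym", "gis_asym")
THREE_PHASES = ("S1", "T1", "T2")


@dataclass(frozen=True)
class StudyConfig:
    """Analysis settings; echoed into every output for provenance."""

    quotient_low: float = 0.8
    quotient_high: float = 1.2
    sd_denominator: str = "off_li"
    mcnemar_variant: str = "chi2"
    alpha: float = 0.05
    signals: tuple[str, ...] = ("rr", "sbp", "dbp", "pp")
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.quotient_low < 1 < self.quotient_high):
            raise ValueError("quotient thresholds must satisfy 0 < low < 1 < high")
        if self.sd_denominator not in ("off_li", "all_points"):
            raise ValueError("sd_denominator must be 'off_li' or 'all_points'")
        if self.mcnemar_variant not in ("chi2", "chi2_corrected", "exact"):
            raise ValueError("unknown mcnemar variant")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        bad = [s for s in self.signals if s not in ("rr", "sbp", "dbp", "pp")]
        if bad:
            raise ValueError(f"unknown signals {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "signals" in data:
            data["signals"] = tuple(data["signals"])
        return cls(**data)


class TiltStudy:
    """A tilt-test asymmetry study over one cohort of beat-to-beat recordings."""

    def __init__(
        self,
        subjects: list[tuple[BeatSeries, PhaseAnnotation]],
        config: StudyConfig | None = None,
    ) -> None:
        if not subjects:
            raise ValueError("empty cohort")
        self.subjects = list(subjects)
        self.config = config or StudyConfig()

    @classmethod
    def from_directory(cls, directory: str | Path, config: StudyConfig | None = None) -> "TiltStudy":
        """Load ``<id>.csv`` + ``<id>_phases.yaml`` pairs plus a ``design.csv``
        mapping subject ids to groups (columns ``subject,group``)."""
        directory = Path(directory)
        design = pd.read_csv(directory / "design.csv", dtype=str)
        subjects = []
        for _, row in design.iterrows():
            sid = row["subject"]
            series = read_beat_series(directory / f"{sid}.csv", subject_id=sid, group=Group(row["group"]))
            annotation = read_phase_annotation(directory / f"{sid}_phases.yaml")
            subjects.append((series, annotation))
        return cls(subjects, config=config)

    @classmethod
    def from_records(cls, records, config: StudyConfig | None = None) -> "TiltStudy":
        """Build from :class:`~tiltasym.synthetic.SubjectRecord` objects."""
        return cls([(r.series, r.annotation) for r in records], config=config)

    def fit(self) -> "StudyResults":
        cfg = self.config
        excl_rows, summaries, flag_rows = [], [], []
        for series, annotation in self.subjects:
            report = quotient_filter(series.rr, cfg.quotient_low, cfg.quotient_high)
            decision = check_exclusion(series, annotation, report)
            excl_rows.append(
                {
                    "subject": series.subject_id,
                    "group": series.group.value,
                    "n_beats": report.n_beats,
                    "n_flagged": report.n_flagged,
                    "fraction_flagged": report.fraction_flagged,
                    "bp_missing_fraction": series.bp_missing_fraction,
                    "excluded": decision.excluded,
                    "reasons": ";".join(r.value for r in decision.reasons),
                }
            )
            if decision.excluded:
                continue
            censored = censor_beats(series, report)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                segments = extract_segments(censored, annotation)
                for seg in segments.values():
                    for signal in cfg.signals:
                        summ = summarize_segment(seg, signal, cfg.sd_denominator)
                        summaries.append(summ)
                        flags = classify_asymmetry(summ)
                        flag_rows.append(
                            {
                                "subject": summ.subject,
                                "group": summ.group,
                                "phase": summ.phase,
                                "signal": summ.signal,
                                **{c: getattr(flags, c) for c in INDEX_CRITERIA},
                            }
                        )
        descriptors = pd.DataFrame([asdict(s) for s in summaries])
        exclusions = pd.DataFrame(excl_rows)
        flags = pd.DataFrame(flag_rows)
        for g in (Group.VVS_POS, Group.VVS_NEG):
            kept = exclusions[(exclusions["group"] == g.value) & (~exclusions["excluded"])]
            if len(kept) < 2:
                raise ValueError(f"group {g.value}: fewer than 2 subjects after exclusion")

        group_cmp = self._group_comparison(descriptors)
        within = self._within_group(descriptors)
        friedman_tbl = self._friedman_three_phase(descriptors)
        occurrence, contingency = tabulate_occurrence(flags)
        occ_tests = self._occurrence_tests(flags)
        log = {
            "package_version": __version__,
            "config": {**asdict(cfg), "signals": list(cfg.signals)},
            "n_subjects": len(self.subjects),
            "n_excluded": int(exclusions["excluded"].sum()),
        }
        return StudyResults(
            config=cfg,
            descriptors=descriptors,
            exclusions=exclusions,
            flags=flags,
            group_comparison=group_cmp,
            within_group=within,
            friedman_table=friedman_tbl,
            occurrence=occurrence,
            contingency=contingency,
            occurrence_tests=occ_tests,
            log=log,
        )

    # -- statistical families ------------------------------------------------

    def _group_comparison(self, desc: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for phase in ("S", "T"):
            sub = desc[desc["phase"] == phase]
            for signal in self.config.signals:
                ss = sub[sub["signal"] == signal]
                for measure in MEASURES:
                    pos = ss.loc[ss["group"] == Group.VVS_POS.value, measure].dropna()
                    neg = ss.loc[ss["group"] == Group.VVS_NEG.value, measure].dropna()
                    if len(pos) < 2 or len(neg) < 2:
                        continue
                    res = mann_whitney(pos, neg)
                    rows.append(
                        {
                            "phase": phase, "signal": signal, "measure": measure,
                            "median_pos": float(np.median(pos)), "median_neg": float(np.median(neg)),
                            "statistic": res.statistic, "p": res.p_raw, "method": res.method,
                        }
                    )
        return pd.DataFrame(rows)

    def _within_group(self, desc: pd.DataFrame) -> pd.DataFrame:
        rows = []
        wide = desc.pivot_table(
            index=["subject", "group", "signal"], columns="phase", values=list(MEASURES), aggfunc="first"
        )
        for group in (Group.VVS_NEG.value, Group.VVS_POS.value):
            for signal in self.config.signals:
                for measure in MEASURES:
                    try:
                        s_vals = wide.loc[(slice(None), group, signal), (measure, "S")]
                        t_vals = wide.loc[(slice(None), group, signal), (measure, "T")]
                    except KeyError:
                        continue
                    paired = pd.concat([s_vals, t_vals], axis=1).dropna()
                    if len(paired) < 2:
                        continue
                    diffs = paired.iloc[:, 0].to_numpy() - paired.iloc[:, 1].to_numpy()
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = wilcoxon_signed_rank(diffs)
                    rows.append(
                        {
                            "group": group, "signal": signal, "measure": measure,
                            "median_S": float(paired.iloc[:, 0].median()),
                            "median_T": float(paired.iloc[:, 1].median()),
                            "n_pairs": len(paired),
                            "statistic": res.statistic, "p": res.p_raw, "method": res.method,
                        }
                    )
        return pd.DataFrame(rows)

    def _friedman_three_phase(self, desc: pd.DataFrame) -> pd.DataFrame:
        rows = []
        pos = desc[desc["group"] == Group.VVS_POS.value]
        for signal in self.config.signals:
            ss = pos[pos["signal"] == signal]
            wide = ss.pivot_table(index="subject", columns="phase", values=list(MEASURES), aggfunc="first")
            for measure in MEASURES:
                try:
                    block = wide[measure][list(THREE_PHASES)].dropna()
                except KeyError:
                    continue
                if len(block) < 2:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    omnibus, posthoc = friedman_with_posthoc(block.to_numpy(), THREE_PHASES)
                rows.append(
                    {
                        "signal": signal, "measure": measure, "n": len(block),
                        "friedman_p": omnibus.p_raw,
                        "p_S1_T1": posthoc[0].p_adjusted,
                        "p_S1_T2": posthoc[1].p_adjusted,
                        "p_T1_T2": posthoc[2].p_adjusted,
                        "method": omnibus.method,
                    }
                )
        return pd.DataFrame(rows)

    def _occurrence_tests(self, flags: pd.DataFrame) -> pd.DataFrame:
        rows = []
        pos = flags[flags["group"] == Group.VVS_POS.value]
        for signal in self.config.signals:
            ss = pos[pos["signal"] == signal]
            for criterion in INDEX_CRITERIA:
                wide = ss.pivot_table(index="subject", columns="phase", values=criterion, aggfunc="first")
                if not set(THREE_PHASES).issubset(wide.columns):
                    continue
                block = wide[list(THREE_PHASES)].dropna().astype(int)
                if len(block) < 2:
                    continue
                pattern = ThreeWayPattern.from_matrix(block.to_numpy(), THREE_PHASES)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    omnibus, posthoc = cochran_q_with_posthoc(pattern, variant=self.config.mcnemar_variant)
                rows.append(
                    {
                        "signal": signal, "criterion": criterion, "n": pattern.n,
                        "cochran_q": omnibus.statistic, "cochran_q_p": omnibus.p_raw,
                        "p_S1_T1": posthoc[0].p_adjusted,
                        "p_S1_T2": posthoc[1].p_adjusted,
                        "p_T1_T2": posthoc[2].p_adjusted,
                        "method": f"{omnibus.method} + mcnemar {self.config.mcnemar_variant} (holm)",
                    }
                )
        return pd.DataFrame(rows)


def tabulate_occurrence(flags: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Occurrence proportions per phase and pairwise 2×2 paired tables.

    ``flags`` has columns subject/group/phase/signal plus the boolean
    criteria columns.  Proportions are rounded to one decimal (report
    convention); the tables keep exact counts.  Subjects missing one phase
    of a pair are dropped from that pair only.
    """
    prop_rows = []
    tables: dict[tuple[str, str, str, str, str], PairedTable] = {}
    for (group, signal), sub in flags.groupby(["group", "signal"]):
        for criterion in INDEX_CRITERIA:
            wide = sub.pivot_table(index="subject", columns="phase", values=criterion, aggfunc="first")
            for phase in wide.columns:
                col = wide[phase].dropna()
                if len(col) == 0:
                    continue
                prop_rows.append(
                    {
                        "group": group, "signal": signal, "criterion": criterion, "phase": phase,
                        "n": len(col), "n_asym": int(col.sum()),
                        # half-up to one decimal (report convention: 9/16 → 56.3)
                        "percent": math.floor(1000.0 * float(col.mean()) + 0.5) / 10.0,
                    }
                )
            phases = [p for p in ("S", "T", "S1", "T1", "T2") if p in wide.columns]
            for i in range(len(phases)):
                for j in range(i + 1, len(phases)):
                    pair = wide[[phases[i], phases[j]]].dropna().astype(int)
                    if len(pair) == 0:
                        continue
                    f, s = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
                    tables[(group, signal, criterion, phases[i], phases[j])] = PairedTable(
                        labels=(phases[i], phases[j]),
                        a=int(np.sum((f == 1) & (s == 1))),
                        b=int(np.sum((f == 1) & (s == 0))),
                        c=int(np.sum((f == 0) & (s == 1))),
                        d=int(np.sum((f == 0) & (s == 0))),
                    )
    return pd.DataFrame(prop_rows), tables


@dataclass
class StudyResults:
    """Fitted study: report tables, audit trail and serialization."""

    config: StudyConfig
    descriptors: pd.DataFrame
    exclusions: pd.DataFrame
    flags: pd.DataFrame
    group_comparison: pd.DataFrame
    within_group: pd.DataFrame
    friedman_table: pd.DataFrame
    occurrence: pd.DataFrame
    contingency: dict
    occurrence_tests: pd.DataFrame
    log: dict = field(default_factory=dict)

    def summary(self) -> str:
        """Plain-text digest of the study, display-rounded to 3 decimals."""
        lines = [
            "Tilt-test variability/asymmetry study",
            f"  subjects: {self.log.get('n_subjects')} (excluded: {self.log.get('n_excluded')})",
            f"  config: {self.log.get('config')}",
            "",
            "Within-group supine vs tilt (Wilcoxon):",
            self.within_group.round(3).to_string(index=False),
            "",
            "Between-group comparisons (Mann-Whitney):",
            self.group_comparison.round(3).to_string(index=False),
            "",
            "Vasovagal S1/T1/T2 (Friedman + Holm post-hoc):",
            self.friedman_table.round(3).to_string(index=False),
            "",
            "Asymmetry occurrence (percent per phase):",
            self.occurrence.to_string(index=False),
            "",
            "Occurrence tests (Cochran Q + Holm-corrected McNemar):",
            self.occurrence_tests.round(3).to_string(index=False),
        ]
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.exclusions.to_csv(outdir / "exclusions.csv", index=False)
        self.descriptors.to_csv(outdir / "descriptors.csv", index=False)
        self.flags.to_csv(outdir / "asymmetry_flags.csv", index=False)
        self.group_comparison.to_csv(outdir / "group_comparison.csv", index=False)
        self.within_group.to_csv(outdir / "within_group.csv", index=False)
        self.friedman_table.to_csv(outdir / "friedman_three_phase.csv", index=False)
        self.occurrence.to_csv(outdir / "occurrence_proportions.csv", index=False)
        self.occurrence_tests.to_csv(outdir / "occurrence_tests.csv", index=False)
        cont_rows = [
            {"group": g, "signal": s, "criterion": c, "phase_1": p1, "phase_2": p2,
             "a": t.a, "b": t.b, "c": t.c, "d": t.d}
            for (g, s, c, p1, p2), t in self.contingency.items()
        ]
        pd.DataFrame(cont_rows).to_csv(outdir / "contingency_tables.csv", index=False)
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(self.log, fh, indent=2)
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")


def run_study(subjects: list[tuple[BeatSeries, PhaseAnnotation]], config: StudyConfig | None = None) -> StudyResults:
    """Functional wrapper: ``TiltStudy(subjects, config).fit()``."""
    return TiltStudy(subjects, config=config).fit()
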