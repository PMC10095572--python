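"""End-to-end orchestration: simulate/load → spectral → ERD → statistics.

``run_analysis`` drives the whole pipeline from a :class:`RunConfig` that
either points at recordings on disk (EDF or fixture files plus a metadata CSV)
or embeds a :class:`~alphaerd.cohort.CohortSpec` to simulate.  It produces the
band-power and ERD tables, a :class:`StatReport` for the full cohort and for
the age-filtered subcohort (default 30–80 years), and a manifest with config
hash and output checksums.  Given the same inputs, config and seed the outputs
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sstats

from . import __version__
from .cohort import CohortSpec, generate_profiles, iter_cohort, profiles_to_frame
from .eeg_io import (
    genotype_group,
    load_metadata,
    read_recording,
    select_frontal,
    write_metadata,
    write_recording,
)
from .erd import erd_table, region_power
from .spectral import (
    DEFAULT_BANDS,
    InsufficientDataError,
    recording_band_powers,
)
from .stats import (
    DegenerateDataError,
    duncan_posthoc,
    glm_genotype_effect,
    one_sample_erd_test,
    pearson_age_correlation,
    shapiro_wilk_screen,
)

logger = logging.getLogger("alphaerd")

__all__ = ["RunConfig", "StatReport", "RunResult", "run_analysis", "simulate_to_dir",
           "build_stat_report", "compute_erd_tables"]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    Exactly one of ``simulation`` (a CohortSpec) and ``input_dir`` +
    ``metadata_path`` must be set.
    """

    simulation: CohortSpec | None = None
    input_dir: str | None = None
    metadata_path: str | None = None
    input_format: str = "fixture"  # or "edf" for on-disk recordings
    epoch_len_s: float = 4.0
    p2p_threshold_uV: float = 100.0
    min_epochs: int = 30
    window: str = "rect"
    per_channel_erd: bool = False  # sensitivity variant: per-channel ERD averaged
    one_sample_method: str = "t"  # or "wilcoxon"
    holm: bool = False  # Holm-adjusted p columns in one-sample/GLM tables
    age_filter: tuple[int, int] | None = (30, 80)
    out_dir: str | None = None
    seed: int | None = None  # overrides simulation.seed when set

    def validate(self) -> None:
        has_sim = self.simulation is not None
        has_files = self.input_dir is not None or self.metadata_path is not None
        if has_sim == has_files:
            raise ValueError("exactly one of simulation spec and input paths must be set")
        if has_files and (self.input_dir is None or self.metadata_path is None):
            raise ValueError("file input needs both input_dir and metadata_path")
        if self.age_filter is not None:
            lo, hi = self.age_filter
            if not (19 <= lo <= hi <= 80):
                raise ValueError("age_filter bounds must lie within [19, 80]")

    # YAML round trip -------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        if self.age_filter is not None:
            d["age_filter"] = list(self.age_filter)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = CohortSpec.from_dict(d["simulation"])
        if d.get("age_filter") is not None:
            d["age_filter"] = tuple(d["age_filter"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class StatReport:
    """Tidy result tables of one cohort-level analysis."""

    label: str
    n_subjects: int
    normality: pd.DataFrame
    one_sample: pd.DataFrame
    glm: pd.DataFrame
    posthoc: pd.DataFrame
    correlations: pd.DataFrame
    demographics: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "normality": self.normality,
            "one_sample": self.one_sample,
            "glm": self.glm,
            "posthoc": self.posthoc,
            "correlations": self.correlations,
            "demographics": self.demographics,
        }

    def to_json(self) -> str:
        payload = {"label": self.label, "n_subjects": self.n_subjects,
                   "warnings": self.warnings}
        for name, tab in self.tables().items():
            payload[name] = json.loads(tab.to_json(orient="records", double_precision=12))
        return json.dumps(payload, indent=1)


@dataclass
class RunResult:
    config: RunConfig
    metadata: pd.DataFrame
    band_power: pd.DataFrame
    erd: pd.DataFrame
    reports: dict[str, StatReport]
    manifest: dict
    excluded: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# data acquisition
# ---------------------------------------------------------------------------

def simulate_to_dir(spec: CohortSpec, out_dir, format: str = "edf") -> Path:
    """Write a simulated cohort to disk: recordings plus metadata.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = ".edf" if format == "edf" else ".npz"
    profiles = []
    for profile, rest, task in iter_cohort(spec):
        profiles.append(profile)
        for rec in (rest, task):
            write_recording(rec, out / f"{rec.subject_id}_{rec.condition}{ext}", format)
        logger.info("simulated %s (age %d, %s)", profile.subject_id, profile.age,
                    profile.clu_genotype)
    write_metadata(profiles_to_frame(profiles), out / "metadata.csv")
    return out


def _iter_input(config: RunConfig):
    """Yield (subject_id, rest recording, task recording) per the config source."""
    if config.simulation is not None:
        spec = config.simulation
        if config.seed is not None:
            spec = dataclasses.replace(spec, seed=config.seed)
        meta = genotype_group(profiles_to_frame(generate_profiles(spec)))
        yield meta
        for profile, rest, task in iter_cohort(spec):
            yield profile.subject_id, rest, task
    else:
        meta = genotype_group(load_metadata(config.metadata_path))
        yield meta
        in_dir = Path(config.input_dir)
        ext = ".edf" if config.input_format == "edf" else ".npz"
        for sid in meta["subject_id"]:
            recs = {}
            for cond in ("rest", "task"):
                path = in_dir / f"{sid}_{cond}{ext}"
                recs[cond] = read_recording(path, config.input_format, condition=cond)
            yield sid, recs["rest"], recs["task"]


def compute_erd_tables(config: RunConfig):
    """Spectral reduction and ERD for every subject: (metadata, band_power, erd, excluded)."""
    config.validate()
    stream = _iter_input(config)
    meta = next(stream)
    bp_frames, excluded = [], []
    for sid, rest, task in stream:
        try:
            for rec in (rest, task):
                frame, es = recording_band_powers(
                    select_frontal(rec),
                    bands=DEFAULT_BANDS,
                    epoch_len_s=config.epoch_len_s,
                    p2p_threshold_uV=config.p2p_threshold_uV,
                    min_epochs=config.min_epochs,
                    window=config.window,
                )
                bp_frames.append(frame)
                logger.info(
                    "%s/%s: retained %d epochs (%d rejected)",
                    sid, rec.condition, es.retained_count, es.rejected_count,
                )
        except InsufficientDataError as exc:
            logger.warning("excluding %s: %s", sid, exc)
            excluded.append(sid)
    if not bp_frames:
        raise InsufficientDataError("no subject produced usable epochs")
    band_power = pd.concat(bp_frames, ignore_index=True)
    band_power = band_power[~band_power["subject_id"].isin(excluded)]
    meta = meta[~meta["subject_id"].isin(excluded)].reset_index(drop=True)
    regions = region_power(band_power)
    erd = erd_table(regions, per_channel_input=band_power, per_channel=config.per_channel_erd)
    return meta, band_power, erd, excluded


# ---------------------------------------------------------------------------
# statistics assembly
# ---------------------------------------------------------------------------

def build_stat_report(
    meta: pd.DataFrame,
    erd: pd.DataFrame,
    label: str = "full",
    one_sample_method: str = "t",
    holm: bool = False,
) -> StatReport:
    """All inferential tables for one (sub)cohort.

    ``one_sample_method='wilcoxon'`` swaps the one-sample t for the
    signed-rank test; ``holm=True`` appends Holm-adjusted p-values across the
    band × region families (off by default — none applied, as is conventional
    for this design).
    """
    if "clu_group" not in meta.columns:
        meta = genotype_group(meta)
    data = erd.merge(meta, on="subject_id", validate="many_to_one")
    notes: list[str] = []

    norm_rows, one_rows, corr_rows = [], [], []
    for (grp, band, region), sub in data.groupby(["clu_group", "band", "region"]):
        vals = sub["erd_percent"].to_numpy()
        base = {"clu_group": grp, "band": band, "region": region, "n": len(vals)}
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                w, p_norm = shapiro_wilk_screen(vals, label=f"{grp}/{band}/{region}")
            notes.extend(str(c.message) for c in caught)
            norm_rows.append({**base, "W": w, "p": p_norm})
        except (ValueError, DegenerateDataError) as exc:
            norm_rows.append({**base, "W": np.nan, "p": np.nan})
            notes.append(f"normality screen degenerate for {grp}/{band}/{region}: {exc}")
        try:
            t, df, p = one_sample_erd_test(vals, method=one_sample_method)
            one_rows.append({**base, "mean_erd": vals.mean(),
                             "se": vals.std(ddof=1) / np.sqrt(len(vals)),
                             "t": t, "df": df, "p": p})
        except (ValueError, DegenerateDataError) as exc:
            notes.append(f"one-sample test skipped for {grp}/{band}/{region}: {exc}")
        try:
            res = pearson_age_correlation(
                sub["age"], vals, pair=f"age vs {band} ERD ({grp}, {region})"
            )
            corr_rows.append({**base, "pair": res.pair, "r": res.r, "p": res.p})
        except (ValueError, DegenerateDataError) as exc:
            notes.append(f"correlation skipped for {grp}/{band}/{region}: {exc}")
    for grp, sub in meta.groupby("clu_group"):
        if len(sub) >= 3 and sub["lft_words"].std() > 0:
            res = pearson_age_correlation(
                sub["age"], sub["lft_words"], pair=f"age vs LFT words ({grp})"
            )
            corr_rows.append({"clu_group": grp, "band": "", "region": "",
                              "n": res.n, "pair": res.pair, "r": res.r, "p": res.p})

    glm_rows, post_rows = [], []
    for band, sub in data.groupby("band"):
        variants = {"both": sub.groupby(
            ["subject_id", "clu_group", "apoe_group", "sex", "age"], as_index=False
        )["erd_percent"].mean()}
        for region, rsub in sub.groupby("region"):
            variants[region] = rsub
        for region_label, frame in variants.items():
            try:
                res = glm_genotype_effect(frame)
            except ValueError as exc:
                notes.append(f"GLM skipped for {band}/{region_label}: {exc}")
                continue
            glm_rows.append({"band": band, "region": region_label, "factor": "clu_group",
                             "F": res.F, "df_num": res.df_num, "df_den": res.df_den,
                             "p": res.p, "n": res.n})
            if region_label == "both":
                continue
            groups = frame.groupby("clu_group")["erd_percent"]
            means = groups.mean().to_dict()
            sizes = groups.size().to_dict()
            if len(means) < 2 or min(sizes.values()) < 2:
                continue
            # within-group (error) mean square from the one-way layout
            resid = frame["erd_percent"] - frame["clu_group"].map(means)
            df_err = len(frame) - len(means)
            mse = float((resid**2).sum() / df_err)
            if mse <= 0:
                continue
            for cmp_res in duncan_posthoc(means, mse, df_err, sizes):
                post_rows.append({"band": band, "region": region_label,
                                  "comparison": cmp_res.comparison,
                                  "mean_difference": cmp_res.mean_difference,
                                  "critical_range": cmp_res.critical_range,
                                  "p": cmp_res.p, "significant": cmp_res.significant})

    demo = _demographics(meta, notes)
    one_sample = pd.DataFrame(one_rows)
    glm = pd.DataFrame(glm_rows)
    if holm:
        from .stats import holm_adjust

        for tab in (one_sample, glm):
            if "p" in tab.columns and len(tab):
                tab["p_holm"] = holm_adjust(tab["p"].to_numpy())
    return StatReport(
        label=label,
        n_subjects=int(meta["subject_id"].nunique()),
        normality=pd.DataFrame(norm_rows),
        one_sample=one_sample,
        glm=glm,
        posthoc=pd.DataFrame(post_rows),
        correlations=pd.DataFrame(corr_rows),
        demographics=demo,
        warnings=notes,
    )


def _demographics(meta: pd.DataFrame, notes: list[str]) -> pd.DataFrame:
    """Group summary rows plus between-group tests (age, sex, APOE, LFT)."""
    rows = []
    groups = {g: sub for g, sub in meta.groupby("clu_group")}
    for g, sub in groups.items():
        rows.append({
            "row": g, "n": len(sub),
            "age_mean": sub["age"].mean(), "age_se": sstats.sem(sub["age"]),
            "gender_m": int((sub["sex"] == "m").sum()),
            "gender_f": int((sub["sex"] == "f").sum()),
            "apoe_e4neg": int((sub["apoe_group"] == "E4-").sum()),
            "apoe_e4pos": int((sub["apoe_group"] == "E4+").sum()),
            "lft_mean": sub["lft_words"].mean(), "lft_se": sstats.sem(sub["lft_words"]),
        })
    if len(groups) == 2:
        (ga, a), (gb, b) = sorted(groups.items())
        p_row = {"row": "p_value", "n": np.nan}
        t_age = sstats.ttest_ind(a["age"], b["age"], equal_var=True)
        p_row["age_mean"] = t_age.pvalue
        from .stats import proportion_test

        for key, col, levels in (
            ("gender_m", "sex", ("m", "f")),
            ("apoe_e4neg", "apoe_group", ("E4-", "E4+")),
        ):
            table = np.array(
                [[int((g[col] == lv).sum()) for lv in levels] for g in (a, b)]
            )
            try:
                _, p = proportion_test(table)
                p_row[key] = p
            except ValueError as exc:
                notes.append(f"proportion test degenerate for {col}: {exc}")
                p_row[key] = np.nan
        t_lft = sstats.ttest_ind(a["lft_words"], b["lft_words"], equal_var=True)
        p_row["lft_mean"] = t_lft.pvalue
        rows.append(p_row)
    else:
        notes.append("demographic tests need exactly two genotype groups")
        rows.append({"row": "p_value", "n": np.nan, "age_mean": np.nan,
                     "gender_m": np.nan, "apoe_e4neg": np.nan, "lft_mean": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run + manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_analysis(config: RunConfig) -> RunResult:
    """Execute the whole pipeline and (optionally) write all outputs to out_dir."""
    config.validate()
    meta, band_power, erd, excluded = compute_erd_tables(config)
    kw = {"one_sample_method": config.one_sample_method, "holm": config.holm}
    reports = {"full": build_stat_report(meta, erd, label="full", **kw)}
    if config.age_filter is not None:
        lo, hi = config.age_filter
        sub_meta = meta[(meta["age"] >= lo) & (meta["age"] <= hi)].reset_index(drop=True)
        sub_erd = erd[erd["subject_id"].isin(sub_meta["subject_id"])]
        label = f"age_{lo}_{hi}"
        if sub_meta["clu_group"].nunique() == 2 and len(sub_meta) >= 10:
            reports[label] = build_stat_report(sub_meta, sub_erd, label=label, **kw)
        else:
            logger.warning("age-filtered subcohort too small for inference (N=%d)",
                           len(sub_meta))

    manifest = {
        "tool": "alphaerd",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "rows": {"metadata": len(meta), "band_power": len(band_power), "erd": len(erd)},
        "excluded_subjects": excluded,
        "warnings": sum((r.warnings for r in reports.values()), []),
        "outputs": {},
    }
    result = RunResult(config=config, metadata=meta, band_power=band_power, erd=erd,
                       reports=reports, manifest=manifest, excluded=excluded)
    if config.out_dir is not None:
        _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: RunResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "metadata.csv": lambda p: result.metadata.to_csv(p, index=False),
        "band_power.csv": lambda p: result.band_power.to_csv(p, index=False,
                                                             float_format="%.10g"),
        "erd.csv": lambda p: result.erd.to_csv(p, index=False, float_format="%.10g"),
    }
    for name, writer in files.items():
        writer(out / name)
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    for label, report in result.reports.items():
        path = stats_dir / f"{label}.json"
        path.write_text(report.to_json())
        for tname, tab in report.tables().items():
            tab.to_csv(stats_dir / f"{label}_{tname}.csv", index=False,
                       float_format="%.10g")
    from .report import make_report

    (out / "report.md").write_text(make_report(result))
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            result.manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
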