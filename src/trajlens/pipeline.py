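"""End-to-end orchestration: config, staged execution, manifest, report.

``run_pipeline`` chains aggregate -> ladder (with polynomial pruning) ->
features -> comparisons -> markers on either real post records or the
built-in synthetic cohort, writing every stage artifact plus a manifest
(config echo, seeds, package version, SHA-256 checksums) so a re-run
with the same seed is byte-identical.  ``summarize`` renders a plain
markdown report of the fitted model, parameter table, comparison grid
and marker table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib.metadata import version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .comparison import comparison_grid
from .features import FeatureMatrix
from .lexicon import parse_lexicon, toy_lexicon
from .markers import DEFAULT_WINDOW, run_marker_cascade
from .periods import default_grid, frame_to_series, series_to_frame
from .selection import prune_polynomials, run_ladder, validate_app
from .simulate import simulate_features, simulate_study_cohort, study_generative_spec
from .zip_model import expected_counts, fit

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "summarize", "share_percent"]


def share_percent(k: int, n: int, digits: int = 2) -> float:
    """Percentage share rounded for reporting, e.g. 18 of 3372 -> 0.53."""
    if n <= 0:
        raise ValueError("n must be positive")
    return round(100.0 * k / n, digits)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    With ``counts_csv``/``posts_jsonl`` unset, the run simulates the
    canonical synthetic cohort of ``n_users`` instead.  Thresholds carry
    the analysis conventions: significance .05, composition floor 5%,
    entropy 0.8, APP 0.7.
    """

    out_dir: str = "run"
    counts_csv: str | None = None
    features_csv: str | None = None
    lexicon_dic: str | None = None
    n_users: int = 2000
    g_min: int = 2
    g_max: int = 5
    n_starts: int = 10
    seed: int = 7
    marker_window: tuple[str, ...] = DEFAULT_WINDOW
    significance: float = 0.05
    composition_floor: float = 0.05
    entropy_floor: float = 0.8
    app_floor: float = 0.7
    run_ladder_stage: bool = True
    cv_folds: int = 10

    def __post_init__(self) -> None:
        for name in ("significance", "composition_floor", "entropy_floor", "app_floor"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1); got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "marker_window" in raw:
            raw["marker_window"] = tuple(raw["marker_window"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_model_json(model, path: Path) -> None:
    payload = {
        "n_groups": model.spec.n_groups,
        "count_orders": list(model.spec.count_orders),
        "inflation_orders": list(model.spec.inflation_orders),
        "time_codes": list(model.spec.time_codes),
        "loglik": model.loglik,
        "aic": model.aic,
        "bic": model.bic,
        "entropy": model.entropy,
        "app": [float(a) for a in model.app],
        "composition": [float(c) for c in model.composition],
        "mixing": [float(w) for w in model.mixing],
        "converged": model.converged,
        "n_users": model.n_users,
        "flags": list(model.flags),
        "groups": [
            {
                "beta": list(p.beta),
                "alpha": list(p.alpha),
                "theta": p.theta,
                "beta_se": list(s.beta),
                "alpha_se": list(s.alpha),
                "beta_p": list(w.beta),
                "alpha_p": list(w.alpha),
            }
            for p, s, w in zip(model.params, model.se, model.wald_p)
        ],
    }
    path.write_text(json.dumps(payload, indent=2, allow_nan=True))


def run_pipeline(config: RunConfig):
    """Execute every stage, persisting artifacts and a checksum manifest.

    Returns the output directory as :class:`~pathlib.Path`.  A stage
    failure raises after persisting the partial outputs produced so far.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = default_grid()
    manifest: dict = {
        "version": version("trajlens"),
        "config": dataclasses.asdict(config),
        "stages": {},
        "checksums": {},
    }
    stage_t0 = time.time()

    def _done(stage: str, *paths: Path) -> None:
        nonlocal stage_t0
        for p in paths:
            manifest["checksums"][p.name] = _sha256(p)
        manifest["stages"][stage] = {"seconds": round(time.time() - stage_t0, 2)}
        logger.info("stage %s done (%.1fs)", stage, time.time() - stage_t0)
        stage_t0 = time.time()

    try:
        # --- aggregate / simulate -----------------------------------------
        lexicon = (
            parse_lexicon(config.lexicon_dic) if config.lexicon_dic else toy_lexicon()
        )
        if config.counts_csv:
            counts = pd.read_csv(config.counts_csv)
            series = frame_to_series(counts, grid)
            Y = np.asarray([s.y for s in series], dtype=int)
            user_ids = [s.user_id for s in series]
            matrix = (
                FeatureMatrix.from_frame(pd.read_csv(config.features_csv))
                if config.features_csv
                else None
            )
        else:
            gspec = study_generative_spec(n_users=config.n_users, seed=config.seed)
            cohort = simulate_study_cohort(gspec)
            Y = cohort.counts
            user_ids = cohort.user_ids
            counts = series_to_frame(cohort.series, grid)
            matrix = simulate_features(cohort)
        counts_path = out / "counts.csv"
        counts.to_csv(counts_path, index=False)
        _done("aggregate", counts_path)

        # --- trajectory model: ladder + pruning ---------------------------
        if config.run_ladder_stage:
            ladder = run_ladder(
                Y,
                range(config.g_min, config.g_max + 1),
                time_codes=grid.time_codes,
                seed=config.seed,
                n_starts=config.n_starts,
            )
            ladder_path = out / "ladder.json"
            ladder_path.write_text(
                json.dumps(
                    {
                        "selected_G": ladder.selected_G,
                        "trace": ladder.selection_trace,
                        "violations": {
                            str(g): v for g, v in ladder.violations.items()
                        },
                        "candidates": {
                            str(g): {
                                "aic": m.aic,
                                "bic": m.bic,
                                "entropy": m.entropy,
                                "composition": [float(c) for c in m.composition],
                            }
                            for g, m in ladder.candidates.items()
                        },
                    },
                    indent=2,
                )
            )
            selected_G = ladder.selected_G
            _done("ladder", ladder_path)
            start_spec = ladder.candidates[selected_G].spec
        else:
            from .zip_model import TrajectorySpec

            start_spec = TrajectorySpec.cubic(config.g_min, grid.time_codes)

        pruned_spec, model = prune_polynomials(
            Y, start_spec, seed=config.seed, n_starts=max(config.n_starts // 3, 1),
            return_model=True,
        )
        app_check = validate_app(model, threshold=config.app_floor)
        model_path = out / "model.json"
        _write_model_json(model, model_path)
        post_path = out / "posteriors.csv"
        post = pd.DataFrame(
            model.posterior,
            columns=[f"group{j + 1}" for j in range(model.spec.n_groups)],
        )
        post.insert(0, "user_id", user_ids)
        post["assignment"] = model.assignment + 1
        post.to_csv(post_path, index=False)
        _done("fit", model_path, post_path)
        if not app_check.passed:
            logger.warning("APP validation failed: %s", "; ".join(app_check.failures))

        # --- features + comparisons + markers -----------------------------
        if matrix is not None:
            feat_path = out / "features.csv"
            matrix.to_frame().to_csv(feat_path, index=False)
            _done("features", feat_path)

            comparisons = comparison_grid(matrix, model.assignment)
            comp_path = out / "comparisons.csv"
            comparisons.to_csv(comp_path, index=False)
            _done("comparisons", comp_path)

            cascade = run_marker_cascade(
                comparisons,
                matrix,
                model.assignment,
                lexicon,
                window=config.marker_window,
                n_folds=config.cv_folds,
                seed=config.seed,
            )
            markers_path = out / "markers.json"
            markers_path.write_text(
                json.dumps(
                    {
                        "stages": {
                            s.stage: list(s.categories) for s in cascade.stages
                        },
                        "audit": cascade.audit.to_dict(orient="records"),
                        "intercept_odds": cascade.model.intercept_odds,
                        "n": cascade.model.n,
                        "markers": cascade.model.table.reset_index().to_dict(
                            orient="records"
                        ),
                    },
                    indent=2,
                )
            )
            markers_csv = out / "markers.csv"
            cascade.model.table.to_csv(markers_csv)
            _done("markers", markers_path, markers_csv)
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def summarize(run_dir: str | Path) -> str:
    """Render a markdown report from a completed run directory.

    Read-only and idempotent; missing artifacts are listed rather than
    fatal.
    """
    run_dir = Path(run_dir)
    lines = ["# trajlens run summary", ""]
    missing = []

    ladder_path = run_dir / "ladder.json"
    if ladder_path.exists():
        ladder = json.loads(ladder_path.read_text())
        lines += ["## Model selection", "",
                  "| Model | AIC | BIC | Entropy | Composition |",
                  "|---|---|---|---|---|"]
        for g, c in sorted(ladder["candidates"].items(), key=lambda kv: int(kv[0])):
            comp = "/".join(f"{100 * x:.2f}%" for x in c["composition"])
            lines.append(
                f"| {g}-group | {c['aic']:.2f} | {c['bic']:.2f} | "
                f"{c['entropy']:.3f} | {comp} |"
            )
        lines += ["", f"Selected: **{ladder['selected_G']} groups**", ""]
    else:
        missing.append("ladder.json")

    model_path = run_dir / "model.json"
    if model_path.exists():
        m = json.loads(model_path.read_text())
        lines += ["## Fitted trajectory model", ""]
        comp_pct = [100 * c for c in m["composition"]]
        lines.append(
            f"- {m['n_groups']} groups on {m['n_users']} users; "
            f"log-likelihood {m['loglik']:.2f}, entropy {m['entropy']:.3f}"
        )
        lines.append(
            "- composition: "
            + " / ".join(f"{c:.2f}%" for c in comp_pct)
            + f" (sum {sum(comp_pct):.2f}%)"
        )
        lines.append("- APP: " + " / ".join(f"{a:.3f}" for a in m["app"]))
        lines += ["", "| Group | Submodel | Term | Estimate | SE | p |",
                  "|---|---|---|---|---|---|"]
        terms = ["Intercept", "Linear", "Quadratic", "Cubic"]
        for j, grp in enumerate(m["groups"], start=1):
            for part, est_k, se_k, p_k in (
                ("count", "beta", "beta_se", "beta_p"),
                ("inflation", "alpha", "alpha_se", "alpha_p"),
            ):
                for t, est in enumerate(grp[est_k]):
                    se = grp[se_k][t]
                    p = grp[p_k][t]
                    se_s = f"{se:.3f}" if se == se else "--"
                    p_s = f"{p:.4f}" if p == p else "--"
                    lines.append(
                        f"| {j} | {part} | {terms[t]} | {est:.3f} | {se_s} | {p_s} |"
                    )
        lines.append("")
    else:
        missing.append("model.json")

    comp_path = run_dir / "comparisons.csv"
    if comp_path.exists():
        df = pd.read_csv(comp_path)
        ok = df[df["status"] == "ok"]
        lines += ["## Between-group rate ratios (low-risk reference)", "",
                  f"{len(ok)} of {len(df)} category-period cells estimated; "
                  f"{int((ok['p'] <= 0.05).sum())} significant at p <= .05.", ""]
    else:
        missing.append("comparisons.csv")

    markers_path = run_dir / "markers.json"
    if markers_path.exists():
        mk = json.loads(markers_path.read_text())
        lines += ["## Linguistic markers (multivariate logistic)", "",
                  "| Marker | OR | SE(log) | p | direction |", "|---|---|---|---|---|"]
        for row in mk["markers"]:
            lines.append(
                f"| {row['marker']} | {row['odds_ratio']:.2f} | {row['se']:.2f} | "
                f"{row['p']:.4f} | {row['direction']} |"
            )
        lines.append("")
    else:
        lines += ["## Linguistic markers", "", "section unavailable", ""]
        missing.append("markers.json")

    if missing:
        lines += ["## Missing artifacts", ""] + [f"- {m}" for m in missing] + [""]
    return "\n".join(lines)
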