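"""Stepwise QTL detection for MAGIC populations.

The scan machinery implements funnel-weighted single-marker regression and
founder-haplotype-probability regression, recursive forward selection
against a Bonferroni threshold derived from the effective number of
independent haplotype blocks, Benjamini-Hochberg FDR confidence tagging at
addition time, backward elimination under a per-parameter AIC penalty, and
reporting of QTL support intervals, variance explained and eight-founder
effect vectors.

Multiple-testing arithmetic defaults: 237.19 effective haplotype blocks
(21 chromosomes + 4 recombination events per chromosome over a 54.05
Morgan map), giving addition threshold p < 0.1/237.19 = 4.2e-4 and drop
threshold p > 0.05/237.19 = 2.1e-4; the latter corresponds to a
per-parameter AIC penalty k = 13.73 through the chi-square(1) quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import FounderProbabilityGrid, GeneticMap

# ---------------------------------------------------------------------------
# multiple-testing plan
# ---------------------------------------------------------------------------


def estimate_n_blocks(
    n_chromosomes: int = 21,
    recomb_per_chromosome: float = 4.0,
    map_length_morgans: float = 54.05,
) -> float:
    """Effective number of independent haplotype blocks genome-wide.

    One block per chromosome plus the expected recombination events
    accumulated over the map: ``n_chromosomes + rate * length``.  At the
    defaults this gives 21 + 4 x 54.05 = 237.2 blocks.
    """
    if n_chromosomes <= 0 or recomb_per_chromosome < 0 or map_length_morgans < 0:
        raise ValueError("block-count inputs must be positive")
    return float(n_chromosomes + recomb_per_chromosome * map_length_morgans)


def bonferroni_threshold(alpha: float, n_blocks: float) -> float:
    """Genome-wide p threshold alpha / n_blocks."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    return alpha / n_blocks


def penalty_to_p(k: float, df: int = 1) -> float:
    """P-value equivalent of a per-parameter AIC penalty k on a df-term.

    A term of ``df`` parameters survives elimination when dropping it
    raises -2*loglik by more than k*df; the matched single-test p-value is
    the chi-square(df) upper tail at k*df.
    """
    if k < 0 or df < 1:
        raise ValueError("need k >= 0 and df >= 1")
    return float(stats.chi2.sf(k * df, df))


def p_to_penalty(p: float, df: int = 1) -> float:
    """Inverse of :func:`penalty_to_p`: per-parameter penalty matching p."""
    if not 0 < p <= 1 or df < 1:
        raise ValueError("need p in (0, 1] and df >= 1")
    return float(stats.chi2.isf(p, df) / df)


@dataclass
class MultipleTestingPlan:
    """Thresholds controlling forward addition and backward elimination."""

    n_blocks: float = field(default_factory=estimate_n_blocks)
    alpha_add: float = 0.1
    alpha_drop: float = 0.05
    aic_penalty_snp: float = 13.73
    aic_penalty_hap: float = 5.0
    max_qtl: int = 30

    def __post_init__(self) -> None:
        if self.p_add <= self.p_drop:
            raise ValueError("addition threshold must exceed drop threshold")
        if self.aic_penalty_snp <= 0 or self.aic_penalty_hap <= 0:
            raise ValueError("AIC penalties must be positive")

    @property
    def p_add(self) -> float:
        return bonferroni_threshold(self.alpha_add, self.n_blocks)

    @property
    def p_drop(self) -> float:
        return bonferroni_threshold(self.alpha_drop, self.n_blocks)


# ---------------------------------------------------------------------------
# funnel weights
# ---------------------------------------------------------------------------


def funnel_weights(funnel_ids, mode: str = "inverse") -> np.ndarray:
    """Per-line regression weights adjusting for funnel structure.

    ``mode="inverse"`` (default) weights each line by the reciprocal of
    its funnel's line count, so every funnel contributes equal total
    weight; ``mode="proportional"`` weights by the count itself (the
    alternative reading of weighting "by the number of lines per
    funnel").  Weights are normalised to mean 1 so the effective sample
    size is preserved.
    """
    s = pd.Series(funnel_ids)
    counts = s.map(s.value_counts()).to_numpy(dtype=float)
    if mode == "inverse":
        w = 1.0 / counts
    elif mode == "proportional":
        w = counts
    else:
        raise ValueError("weighting mode must be 'inverse' or 'proportional'")
    return w / w.mean()


# ---------------------------------------------------------------------------
# weighted least squares engine
# ---------------------------------------------------------------------------


class _WLS:
    """Residualising projector for weighted least squares.

    Holds the QR factorisation of the sqrt-weighted base design (intercept
    + fixed terms); mapping any column through :meth:`resid` leaves the
    component orthogonal to the base, from which partial F tests follow.
    """

    def __init__(self, y: np.ndarray, X0: np.ndarray, w: np.ndarray):
        self.n = len(y)
        self.sw = np.sqrt(w)
        Xs = self.sw[:, None] * X0
        self.Q, R = np.linalg.qr(Xs)
        self.p0 = int(np.linalg.matrix_rank(R))
        self.y_r = self._project_out(self.sw * y)
        self.rss0 = float(self.y_r @ self.y_r)

    def _project_out(self, M: np.ndarray) -> np.ndarray:
        return M - self.Q @ (self.Q.T @ M)

    def resid(self, M: np.ndarray) -> np.ndarray:
        """Residualise raw columns (applies sqrt-weights internally)."""
        if M.ndim == 1:
            M = M[:, None]
        return self._project_out(self.sw[:, None] * M)


def _f_pvalue(rss0, rss1, df1, dfres):
    if dfres <= 0 or rss1 <= 0:
        return 0.0 if rss0 > rss1 else 1.0
    F = ((rss0 - rss1) / df1) / (rss1 / dfres)
    return float(stats.f.sf(max(F, 0.0), df1, dfres))


def single_marker_scan(
    y: np.ndarray,
    genotypes: pd.DataFrame,
    gmap: GeneticMap,
    weights: np.ndarray | None = None,
    fixed_markers: list[str] | None = None,
) -> pd.DataFrame:
    """Funnel-weighted single-marker regression scan.

    Each marker is tested by weighted least squares of the trait on the
    marker conditional on the intercept and any previously selected
    markers (1-df partial F test).  Markers already in ``fixed_markers``
    are skipped (p = NaN); markers monomorphic after conditioning are
    forced to p = 1 and flagged, keeping the profile aligned to the map.

    Returns a profile with columns ``marker_id, chrom, cM, stat, df, p,
    neglog10p, effect, flag``.
    """
    y = np.asarray(y, dtype=float)
    if np.sum(np.isfinite(y)) < 30:
        raise ValueError("need finite trait values for at least 30 lines")
    marker_ids = gmap.markers["marker_id"].tolist()
    G = genotypes[marker_ids].to_numpy(dtype=float)
    keep = np.isfinite(y)
    y, G = y[keep], G[keep]
    w = np.ones(len(y)) if weights is None else np.asarray(weights, float)[keep]
    fixed_markers = fixed_markers or []
    # mean-impute missing genotype calls for scanning
    if np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), col_mean[None, :], G)
    fixed_idx = [marker_ids.index(m) for m in fixed_markers]
    X0 = np.column_stack([np.ones(len(y))] + [G[:, j] for j in fixed_idx])
    wls = _WLS(y, X0, w)
    Gr = wls.resid(G)
    sxx = np.einsum("ij,ij->j", Gr, Gr)
    sxy = Gr.T @ wls.y_r
    dfres = wls.n - wls.p0 - 1
    ok = sxx > 1e-10 * max(wls.n, 1)
    beta = np.zeros(G.shape[1])
    beta[ok] = sxy[ok] / sxx[ok]
    rss1 = np.maximum(wls.rss0 - beta * sxy, 0.0)  # guard FP cancellation at perfect fit
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (wls.rss0 - rss1) / (rss1 / dfres)
    p = np.ones(G.shape[1])
    p[ok] = stats.f.sf(F[ok], 1, dfres)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    prof = gmap.markers[["marker_id", "chrom", "cM"]].reset_index(drop=True)
    prof["stat"] = np.where(ok, F, 0.0)
    prof["df"] = 1
    prof["p"] = p
    prof["neglog10p"] = -np.log10(p)
    prof["effect"] = beta
    prof["flag"] = np.where(ok, "", "monomorphic")
    if fixed_idx:
        prof.loc[fixed_idx, ["p", "neglog10p", "stat"]] = [np.nan, np.nan, np.nan]
        prof.loc[fixed_idx, "flag"] = "fixed"
    return prof


def haplotype_scan(
    y: np.ndarray,
    grid: FounderProbabilityGrid,
    weights: np.ndarray | None = None,
    fixed_positions: list[int] | None = None,
) -> pd.DataFrame:
    """Founder-haplotype probability scan on the cM grid.

    At each grid position the trait is regressed on the eight founder
    probability columns (weighted), conditional on the intercept and the
    probability blocks of previously selected positions.  The sum-to-one
    constraint leaves 7 estimable contrasts, tested jointly (7-df F test);
    a locally absent founder reduces the rank and the df accordingly, and
    such positions are flagged.  Founder coefficients are re-expressed as
    a centered 8-vector, invariant to the dropped-column choice.

    Returns a profile with columns ``grid_index, chrom, cM, stat, df, p,
    neglog10p, effect, founder_effects, flag``.
    """
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    probs = grid.probs
    if probs.shape[0] != len(y):
        raise ValueError("grid and trait vector disagree on line count")
    if not np.allclose(probs[0].sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("founder probability rows must sum to 1")
    y = y[keep]
    if not keep.all():
        probs = probs[keep]
    w = np.ones(len(y)) if weights is None else np.asarray(weights, float)[keep]
    fixed_positions = fixed_positions or []
    n_f = probs.shape[2]
    blocks = [np.ones((len(y), 1))]
    for j in fixed_positions:
        blocks.append(probs[:, j, : n_f - 1])  # drop-one to avoid exact collinearity
    X0 = np.column_stack(blocks)
    wls = _WLS(y, X0, w)
    dfres_base = wls.n - wls.p0
    records = []
    fixed = set(fixed_positions)
    for j in range(grid.n_positions):
        if j in fixed:
            records.append((j, np.nan, 0, np.nan, np.nan, np.zeros(n_f), "fixed"))
            continue
        D = wls.resid(probs[:, j, :])
        beta, rss_arr, rank, _ = np.linalg.lstsq(D, wls.y_r, rcond=1e-8)
        if rank == 0:
            records.append((j, 0.0, 0, 1.0, 0.0, np.zeros(n_f), "degenerate"))
            continue
        fitted = D @ beta
        rss1 = float(wls.rss0 - fitted @ wls.y_r)
        df1 = int(min(rank, n_f - 1))
        dfres = dfres_base - df1
        pval = _f_pvalue(wls.rss0, rss1, df1, dfres)
        pval = min(max(pval, np.finfo(float).tiny), 1.0)
        F = ((wls.rss0 - rss1) / df1) / (rss1 / dfres) if dfres > 0 and rss1 > 0 else np.inf
        centered = beta - beta.mean()
        flag = "" if rank >= n_f - 1 else "rank_deficient"
        records.append((j, F, df1, pval, float(np.ptp(centered)), centered, flag))
    prof = pd.DataFrame(
        records,
        columns=["grid_index", "stat", "df", "p", "effect", "founder_effects", "flag"],
    )
    prof.insert(1, "chrom", grid.positions["chrom"].to_numpy())
    prof.insert(2, "cM", grid.positions["cM"].to_numpy())
    prof["neglog10p"] = -np.log10(prof["p"])
    return prof


# ---------------------------------------------------------------------------
# scan backends (shared interface for forward/backward selection)
# ---------------------------------------------------------------------------


class SnpBackend:
    """Single-marker scan backend; terms are marker ids (1 df each).

    ``founders`` (a FounderSet) is only needed when SNP-mode founder
    effect vectors are requested for co-localization.
    """

    mode = "snp"
    term_df = 1

    def __init__(
        self, genotypes: pd.DataFrame, gmap: GeneticMap, weights=None, founders=None
    ):
        self.genotypes = genotypes
        self.gmap = gmap
        self.weights = weights
        self.founders = founders
        self._marker_ids = gmap.markers["marker_id"].tolist()

    def founder_alleles(self, term) -> np.ndarray:
        if self.founders is None:
            raise ValueError(
                "SNP-mode founder effect vectors need a FounderSet; "
                "pass founders= to SnpBackend"
            )
        return self.founders.alleles[:, self._marker_ids.index(term)]

    def scan(self, y, fixed_terms: list) -> pd.DataFrame:
        prof = single_marker_scan(y, self.genotypes, self.gmap, self.weights, fixed_terms)
        prof["term"] = prof["marker_id"]
        return prof

    def term_columns(self, term) -> np.ndarray:
        col = self.genotypes[term].to_numpy(dtype=float)
        if np.isnan(col).any():
            col = np.where(np.isnan(col), np.nanmean(col), col)
        return col[:, None]

    def penalty(self, plan: MultipleTestingPlan) -> float:
        return plan.aic_penalty_snp

    def term_location(self, term):
        row = self.gmap.markers.set_index("marker_id").loc[term]
        return str(row["chrom"]), float(row["cM"]), term


class HaplotypeBackend:
    """Founder-probability scan backend; terms are grid indices (7 df)."""

    mode = "haplotype"
    term_df = 7

    def __init__(self, grid: FounderProbabilityGrid, weights=None):
        self.grid = grid
        self.weights = weights

    def scan(self, y, fixed_terms: list) -> pd.DataFrame:
        prof = haplotype_scan(y, self.grid, self.weights, fixed_terms)
        prof["term"] = prof["grid_index"]
        return prof

    def term_columns(self, term) -> np.ndarray:
        n_f = self.grid.probs.shape[2]
        return self.grid.probs[:, term, : n_f - 1]

    def penalty(self, plan: MultipleTestingPlan) -> float:
        return plan.aic_penalty_hap

    def term_location(self, term):
        row = self.grid.positions.iloc[term]
        return str(row["chrom"]), float(row["cM"]), f"grid:{row['chrom']}:{row['cM']:g}"


# ---------------------------------------------------------------------------
# forward selection, FDR confidence, backward elimination
# ---------------------------------------------------------------------------


@dataclass
class CandidateQTL:
    """A term added during forward selection, with its addition evidence."""

    term: object
    chrom: str
    pos_cM: float
    peak_label: str
    p_add: float
    p_fdr: float
    confidence: str  # "high" | "low"
    effect: float
    founder_effects: np.ndarray | None
    profile: pd.DataFrame  # the full scan profile of the addition iteration
    order: int


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def fdr_confidence(profile: pd.DataFrame, peak_row: int) -> tuple[float, str]:
    """FDR-adjust the addition iteration's genome scan; label the peak.

    BH is applied to the full vector of testable positions in the scan in
    which the QTL was added; the peak is high confidence iff its adjusted
    p is below 0.05.
    """
    testable = profile["p"].notna()
    adj = np.full(len(profile), np.nan)
    adj[testable.to_numpy()] = bh_adjust(profile.loc[testable, "p"].to_numpy())
    p_fdr = float(adj[peak_row])
    return p_fdr, ("high" if p_fdr < 0.05 else "low")


def _pick_peak(profile: pd.DataFrame, chrom_order: dict) -> int:
    """Global minimum-p row; ties by chromosome order then position."""
    ok = profile["p"].notna()
    sub = profile[ok]
    keys = list(
        zip(
            sub["p"],
            sub["chrom"].map(chrom_order),
            sub["cM"],
        )
    )
    best = min(range(len(keys)), key=keys.__getitem__)
    return int(sub.index[best])


def forward_select(
    y: np.ndarray, backend, plan: MultipleTestingPlan
) -> list[CandidateQTL]:
    """Recursive forward selection of QTL peaks.

    Repeatedly scans conditional on the already-selected peaks, adding the
    global minimum-p position while it beats the Bonferroni addition
    threshold.  Each candidate stores its addition-iteration profile (used
    for FDR confidence and support intervals).
    """
    chrom_order = {
        c: i
        for i, c in enumerate(
            pd.unique(
                backend.gmap.markers["chrom"]
                if hasattr(backend, "gmap")
                else backend.grid.positions["chrom"]
            )
        )
    }
    selected: list[CandidateQTL] = []
    terms: list = []
    while True:
        if len(selected) >= plan.max_qtl:
            raise RuntimeError(
                f"forward selection exceeded max_qtl={plan.max_qtl}; runaway model"
            )
        profile = backend.scan(y, terms)
        row = _pick_peak(profile, chrom_order)
        p = float(profile.loc[row, "p"])
        if not p < plan.p_add:
            break
        p_fdr, conf = fdr_confidence(profile, row)
        chrom, pos, label = backend.term_location(profile.loc[row, "term"])
        founder_eff = (
            np.asarray(profile.loc[row, "founder_effects"])
            if "founder_effects" in profile.columns
            else None
        )
        selected.append(
            CandidateQTL(
                term=profile.loc[row, "term"],
                chrom=chrom,
                pos_cM=pos,
                peak_label=label,
                p_add=p,
                p_fdr=p_fdr,
                confidence=conf,
                effect=float(profile.loc[row, "effect"]),
                founder_effects=founder_eff,
                profile=profile,
                order=len(selected),
            )
        )
        terms.append(profile.loc[row, "term"])
    return selected


@dataclass
class FittedQTLModel:
    """Joint weighted model over the retained QTL terms."""

    candidates: list[CandidateQTL]  # retained, in addition order
    coefficients: dict  # term -> coefficient array
    seq_ss: dict  # term -> sequential (addition-order) sum of squares
    ss_total: float
    rss: float
    adj_r2: float
    n: int
    n_params: int


def _weighted_rss(y, X, w):
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(sw[:, None] * X, sw * y, rcond=None)
    r = sw * y - (sw[:, None] * X) @ beta
    return float(r @ r), beta


def backward_eliminate(
    y: np.ndarray, candidates: list[CandidateQTL], backend, plan: MultipleTestingPlan
) -> FittedQTLModel:
    """Stepwise removal of QTL terms under a per-parameter AIC penalty.

    Criterion = n*log(RSS/n) + k * (model parameters), with k the
    per-parameter penalty of the backend mode.  At each step the removal
    giving the lowest criterion is taken while it improves on keeping the
    model; ties are resolved by removing the later-added term.  Candidates
    keep the confidence label they earned at addition.
    """
    y = np.asarray(y, dtype=float)
    keep_rows = np.isfinite(y)
    yk = y[keep_rows]
    w = (
        np.ones(len(yk))
        if backend.weights is None
        else np.asarray(backend.weights, float)[keep_rows]
    )
    n = len(yk)
    k_pen = backend.penalty(plan)

    def crit(cands: list[CandidateQTL]) -> tuple[float, float]:
        X, _ = _model_matrix_rows(backend, [c.term for c in cands], keep_rows)
        rss, _ = _weighted_rss(yk, X, w)
        n_par = sum(backend.term_columns(c.term).shape[1] for c in cands)
        return n * np.log(max(rss, 1e-300) / n) + k_pen * n_par, rss

    current = list(candidates)
    cur_crit, _ = crit(current)
    while current:
        best = None
        for i in range(len(current)):
            reduced = current[:i] + current[i + 1 :]
            c, _ = crit(reduced)
            # tie rule: prefer removing the later-added member
            key = (c, -current[i].order)
            if best is None or key < best[0]:
                best = (key, i)
        if best is not None and best[0][0] < cur_crit - 1e-9:
            current.pop(best[1])
            cur_crit = best[0][0]
        else:
            break
    # final fit + sequential SS in addition order
    current.sort(key=lambda c: c.order)
    sw = np.sqrt(w)
    ybar = float(np.sum(w * yk) / np.sum(w))
    ss_total = float(np.sum(w * (yk - ybar) ** 2))
    seq_ss: dict = {}
    prev_rss = ss_total
    terms_so_far: list = []
    for c in current:
        terms_so_far.append(c.term)
        X, _ = _model_matrix_rows(backend, terms_so_far, keep_rows)
        rss, _ = _weighted_rss(yk, X, w)
        seq_ss[c.term] = max(prev_rss - rss, 0.0)
        prev_rss = rss
    X, spans = _model_matrix_rows(backend, [c.term for c in current], keep_rows)
    rss, beta = _weighted_rss(yk, X, w)
    n_params = X.shape[1]
    coeffs = {c.term: beta[s : s + width] for c, (s, width) in zip(current, spans)}
    dfres = n - n_params
    if dfres > 0 and ss_total > 0:
        adj_r2 = 1.0 - (rss / dfres) / (ss_total / (n - 1))
    else:
        adj_r2 = np.nan
    return FittedQTLModel(
        current, coeffs, seq_ss, ss_total, rss, float(adj_r2), n, n_params
    )


def _model_matrix_rows(backend, terms, keep_rows):
    cols = [np.ones((int(keep_rows.sum()), 1))]
    spans = []
    start = 1
    for t in terms:
        M = backend.term_columns(t)[keep_rows]
        spans.append((start, M.shape[1]))
        start += M.shape[1]
        cols.append(M)
    return np.hstack(cols), spans


# ---------------------------------------------------------------------------
# intervals, PVE, founder effects, records
# ---------------------------------------------------------------------------


def define_interval(
    profile: pd.DataFrame,
    peak_chrom: str,
    peak_cM: float,
    window_cM: float = 20.0,
    drop_nlp: float = 2.0,
):
    """Support interval: within 20 cM of the peak and within two -log10 p.

    The support set comprises profile positions on the peak chromosome at
    most ``window_cM`` from the peak whose -log10 p is within ``drop_nlp``
    of the peak's; the reported flanks are the nearest positions *outside*
    the support set on each side (None at a chromosome end).

    Returns ``(left, right)`` as (cM, label) tuples or None.
    """
    sub = profile[(profile["chrom"] == peak_chrom) & profile["p"].notna()]
    pos = sub["cM"].to_numpy()
    nlp = sub["neglog10p"].to_numpy()
    peak_rows = np.flatnonzero(np.isclose(pos, peak_cM))
    if peak_rows.size == 0:
        raise ValueError("peak position not found in profile")
    peak_nlp = float(np.max(nlp[peak_rows]))
    in_support = (np.abs(pos - peak_cM) <= window_cM) & (nlp >= peak_nlp - drop_nlp)
    labels = (
        sub["marker_id"].to_numpy()
        if "marker_id" in sub.columns
        else np.array([f"grid:{peak_chrom}:{p:g}" for p in pos])
    )
    left = right = None
    left_mask = (pos < peak_cM) & ~in_support
    if left_mask.any():
        i = np.flatnonzero(left_mask)[np.argmax(pos[left_mask])]
        left = (float(pos[i]), str(labels[i]))
    right_mask = (pos > peak_cM) & ~in_support
    if right_mask.any():
        i = np.flatnonzero(right_mask)[np.argmin(pos[right_mask])]
        right = (float(pos[i]), str(labels[i]))
    return left, right


def variance_explained(model: FittedQTLModel) -> tuple[dict, float]:
    """Per-term PVE% (sequential SS / total SS) and total PVE% (adj R2)."""
    if model.ss_total <= 0:
        raise ValueError("zero total sum of squares: constant trait")
    per_term = {
        t: 100.0 * ss / model.ss_total for t, ss in model.seq_ss.items()
    }
    return per_term, 100.0 * model.adj_r2


def founder_effect_vector(
    candidate: CandidateQTL, model: FittedQTLModel, backend
) -> np.ndarray:
    """Centered eight-founder effect vector at a QTL.

    Haplotype mode: the term's fitted founder coefficients (reference
    founder at 0) centered to sum to zero.  SNP mode: each founder's
    biallelic allele at the peak marker times the fitted marker effect,
    centered — giving the two scans a common vector space for the
    co-localization correlation.
    """
    coef = model.coefficients.get(candidate.term)
    if backend.mode == "haplotype":
        n_f = backend.grid.probs.shape[2]
        full = np.zeros(n_f)
        if coef is not None:
            full[: len(coef)] = coef
        return full - full.mean()
    alleles = backend.founder_alleles(candidate.term)
    effect = float(coef[0]) if coef is not None and len(coef) else 0.0
    v = alleles.astype(float) * effect
    return v - v.mean()


@dataclass
class QTLRecord:
    """One detected QTL with its full evidence trail."""

    trait: str
    year: object
    method: str  # "snp" | "haplotype"
    source: str  # "single-trait" | "pc"
    chrom: str
    peak_cM: float
    peak_label: str
    p_add: float
    p_fdr: float
    confidence: str
    left_cM: float | None
    left_label: str | None
    right_cM: float | None
    right_label: str | None
    pve: float
    total_pve: float
    effect: float
    founder_effects: np.ndarray


def map_qtl(
    y: np.ndarray,
    backend,
    plan: MultipleTestingPlan | None = None,
    trait: str = "trait",
    year: object = "all",
    source: str = "single-trait",
) -> list[QTLRecord]:
    """Full stepwise QTL detection for one trait.

    Forward selection with FDR confidence tagging, backward elimination
    under the mode's AIC penalty, then interval / PVE / founder-effect
    reporting for every retained QTL.
    """
    plan = plan or MultipleTestingPlan()
    candidates = forward_select(y, backend, plan)
    if not candidates:
        return []
    model = backward_eliminate(y, candidates, backend, plan)
    per_term_pve, total_pve = variance_explained(model)
    records = []
    for c in model.candidates:
        left, right = define_interval(c.profile, c.chrom, c.pos_cM)
        fvec = founder_effect_vector(c, model, backend)
        records.append(
            QTLRecord(
                trait=trait,
                year=year,
                method=backend.mode,
                source=source,
                chrom=c.chrom,
                peak_cM=c.pos_cM,
                peak_label=c.peak_label,
                p_add=c.p_add,
                p_fdr=c.p_fdr,
                confidence=c.confidence,
                left_cM=left[0] if left else None,
                left_label=left[1] if left else None,
                right_cM=right[0] if right else None,
                right_label=right[1] if right else None,
                pve=per_term_pve.get(c.term, 0.0),
                total_pve=total_pve,
                effect=c.effect,
                founder_effects=fvec,
            )
        )
    return records
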