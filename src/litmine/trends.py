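"""Per-gene publication/citation series, recurrent forecasting and trendiness.

Series are cumulative by calendar year over ten categories: publications,
reviews, clinical trials, big- and medium-pharma publications, and the five
corresponding citation categories (a citation event takes the category of
the CITING publication and the year of the citing publication, attributed
to the cited publication's gene).

The forecaster is a GRU encoder-decoder preceded by an attention layer
(a learned softmax weighting over encoder states feeding the decoder),
trained with RMSprop on a log-error loss over min-max-scaled series, with
30% of the series reserved for validation.  It is implemented directly on
numpy with analytic backpropagation through time; the desk-scale default is
a single 5-unit GRU per side, with deeper stacks available via ``n_layers``.

Forecast quality is measured with MASE (mean absolute scaled error): the
mean absolute forecast error divided by the error of the naive forecast
that repeats the last training value; 1 is break-even with naive.

Trendiness: genes are binned into five volume bins by their cumulative
publication count at the end of the training window (percentiles 20..100);
within each bin a Gaussian kernel density (bandwidth 0.1) is fitted to the
log2 fold changes f = log2((predicted+1)/(realised+1)), and the trendiness
of a gene is the right-tail probability P(F >= f_gene).  A gene whose
reality outstrips its forecast has a small f and hence a trendiness near 1.
"""

from __future__ import annotations

import copy
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .corpus import CitationGraph, Corpus, PharmaClass
from .disambig import GeneAnnotationSet

logger = logging.getLogger("litmine")

__all__ = [
    "CATEGORIES",
    "assemble_series",
    "GRUForecaster",
    "Forecaster",
    "train_forecaster",
    "mase",
    "compute_trendiness",
]

CATEGORIES = [
    "publications",
    "reviews",
    "trials",
    "pub_big_pharma",
    "pub_med_pharma",
    "citations",
    "cit_reviews",
    "cit_trials",
    "cit_big_pharma",
    "cit_med_pharma",
]


# ---------------------------------------------------------------------------
# Series assembly


def assemble_series(
    annotations: GeneAnnotationSet,
    corpus: Corpus,
    citations: CitationGraph,
    train_end: int = 2013,
    horizon_end: int = 2019,
    start_year: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Cumulative yearly series per gene over the ten categories.

    Publication categories count the gene's annotated publications of each
    kind in their publication year; citation categories count citation
    events in the CITING publication's year, categorised by the citing
    publication's flags.  Genes with no annotated publication are excluded
    with a log message.  Returns gene -> DataFrame (index: years, columns:
    categories), cumulative and non-decreasing.
    """
    years_seen = [
        corpus[p].year
        for docs in annotations.annotations.values()
        for p in docs
        if p in corpus
    ]
    if start_year is None:
        start_year = min(years_seen) if years_seen else train_end
    years = np.arange(start_year, horizon_end + 1)

    cited_to_genes: dict[str, list[str]] = {}
    for gene, docs in annotations.annotations.items():
        for p in docs:
            cited_to_genes.setdefault(p, []).append(gene)

    out: dict[str, pd.DataFrame] = {}
    new_counts: dict[str, pd.DataFrame] = {}
    for gene, docs in annotations.annotations.items():
        dated = [p for p in docs if p in corpus]
        if not dated:
            logger.info("gene %s has no annotated publications; excluded", gene)
            continue
        counts = pd.DataFrame(0, index=years, columns=CATEGORIES, dtype=int)
        for p in dated:
            pub = corpus[p]
            if not (start_year <= pub.year <= horizon_end):
                continue
            counts.at[pub.year, "publications"] += 1
            if pub.is_review:
                counts.at[pub.year, "reviews"] += 1
            if pub.is_trial:
                counts.at[pub.year, "trials"] += 1
            if pub.pharma_class is PharmaClass.BIG:
                counts.at[pub.year, "pub_big_pharma"] += 1
            elif pub.pharma_class is PharmaClass.MEDIUM:
                counts.at[pub.year, "pub_med_pharma"] += 1
        new_counts[gene] = counts

    for citing, cited in citations.edges:
        genes = cited_to_genes.get(cited)
        if not genes or citing not in corpus:
            continue
        citer = corpus[citing]
        if not (start_year <= citer.year <= horizon_end):
            continue
        for gene in genes:
            if gene not in new_counts:
                continue
            counts = new_counts[gene]
            counts.at[citer.year, "citations"] += 1
            if citer.is_review:
                counts.at[citer.year, "cit_reviews"] += 1
            if citer.is_trial:
                counts.at[citer.year, "cit_trials"] += 1
            if citer.pharma_class is PharmaClass.BIG:
                counts.at[citer.year, "cit_big_pharma"] += 1
            elif citer.pharma_class is PharmaClass.MEDIUM:
                counts.at[citer.year, "cit_med_pharma"] += 1

    for gene, counts in new_counts.items():
        out[gene] = counts.cumsum()
    return out


# ---------------------------------------------------------------------------
# GRU encoder-decoder with attention (numpy, analytic BPTT)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _GRULayer:
    """One batched GRU layer with forward caching and analytic backward."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        def init(fan_in, fan_out):
            lim = math.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=(fan_in, fan_out))

        self.params = {
            "Wz": init(in_dim, units), "Uz": init(units, units), "bz": np.zeros(units),
            "Wr": init(in_dim, units), "Ur": init(units, units), "br": np.zeros(units),
            "Wh": init(in_dim, units), "Uh": init(units, units), "bh": np.zeros(units),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.units = units

    def zero_grads(self) -> None:
        for g in self.grads.values():
            g.fill(0.0)

    def step(self, x: np.ndarray, h_prev: np.ndarray):
        p = self.params
        z = _sigmoid(x @ p["Wz"] + h_prev @ p["Uz"] + p["bz"])
        r = _sigmoid(x @ p["Wr"] + h_prev @ p["Ur"] + p["br"])
        c = np.tanh(x @ p["Wh"] + (r * h_prev) @ p["Uh"] + p["bh"])
        h = (1.0 - z) * h_prev + z * c
        return h, (x, h_prev, z, r, c)

    def forward(self, xs: np.ndarray, h0: np.ndarray):
        """xs: (T, B, in_dim) -> states (T, B, units) and caches."""
        h = h0
        states, caches = [], []
        for t in range(xs.shape[0]):
            h, cache = self.step(xs[t], h)
            states.append(h)
            caches.append(cache)
        return np.stack(states), caches

    def _step_backward(self, dh: np.ndarray, cache):
        x, h_prev, z, r, c = cache
        p, g = self.params, self.grads
        dz = dh * (c - h_prev)
        dc = dh * z
        dh_prev = dh * (1.0 - z)

        dc_pre = dc * (1.0 - c * c)
        g["Wh"] += x.T @ dc_pre
        g["Uh"] += (r * h_prev).T @ dc_pre
        g["bh"] += dc_pre.sum(axis=0)
        drh = dc_pre @ p["Uh"].T
        dr = drh * h_prev
        dh_prev += drh * r

        dz_pre = dz * z * (1.0 - z)
        dr_pre = dr * r * (1.0 - r)
        g["Wz"] += x.T @ dz_pre
        g["Uz"] += h_prev.T @ dz_pre
        g["bz"] += dz_pre.sum(axis=0)
        g["Wr"] += x.T @ dr_pre
        g["Ur"] += h_prev.T @ dr_pre
        g["br"] += dr_pre.sum(axis=0)

        dx = dz_pre @ p["Wz"].T + dr_pre @ p["Wr"].T + dc_pre @ p["Wh"].T
        dh_prev += dz_pre @ p["Uz"].T + dr_pre @ p["Ur"].T
        return dx, dh_prev

    def backward(self, d_states: np.ndarray, caches, d_after: np.ndarray):
        """d_states: (T, B, units) grads on each output state; d_after: grad on h_T
        arriving from outside the sequence.  Returns (dxs, dh0)."""
        carry = d_after
        dxs = np.zeros((len(caches),) + caches[0][0].shape)
        for t in range(len(caches) - 1, -1, -1):
            dx, carry = self._step_backward(d_states[t] + carry, caches[t])
            dxs[t] = dx
        return dxs, carry


class GRUForecaster:
    """Sequence-to-sequence GRU forecaster with attention over encoder states.

    Maps an encoder window of ``t_in`` values to a forecast of ``t_out``
    values (both in the transformed training space).  Attention is a learned
    softmax weighting over the top encoder layer's states; the resulting
    context vector is concatenated with the previous output value as the
    decoder input.  Training uses teacher forcing, full-batch RMSprop and a
    mean-squared loss; 30% of series are reserved for validation and the
    parameters with the best validation loss are kept.
    """

    def __init__(
        self,
        t_in: int,
        t_out: int,
        units: int = 5,
        n_layers: int = 1,
        lr: float = 5e-3,
        epochs: int = 300,
        val_fraction: float = 0.3,
        seed: int = 0,
    ):
        self.t_in, self.t_out = t_in, t_out
        self.units, self.n_layers = units, n_layers
        self.lr, self.epochs, self.val_fraction = lr, epochs, val_fraction
        rng = np.random.default_rng(seed)
        self._rng = rng
        self.encoder = [
            _GRULayer(1 if l == 0 else units, units, rng) for l in range(n_layers)
        ]
        dec_in = 1 + units
        self.decoder = [
            _GRULayer(dec_in if l == 0 else units, units, rng) for l in range(n_layers)
        ]
        self.attn = rng.uniform(-0.1, 0.1, size=t_in)
        self.wo = rng.uniform(-0.5, 0.5, size=(units, 1))
        self.bo = np.zeros(1)
        self._opt_state: dict[int, np.ndarray] = {}

    # -- parameter plumbing -------------------------------------------------

    def _param_items(self):
        items = []
        for layer in self.encoder + self.decoder:
            for key in layer.params:
                items.append((layer.params, layer.grads, key))
        return items

    def _snapshot(self):
        return copy.deepcopy(
            {
                "enc": [l.params for l in self.encoder],
                "dec": [l.params for l in self.decoder],
                "attn": self.attn,
                "wo": self.wo,
                "bo": self.bo,
            }
        )

    def _restore(self, snap) -> None:
        for layer, saved in zip(self.encoder, snap["enc"]):
            layer.params = copy.deepcopy(saved)
        for layer, saved in zip(self.decoder, snap["dec"]):
            layer.params = copy.deepcopy(saved)
        self.attn = snap["attn"].copy()
        self.wo = snap["wo"].copy()
        self.bo = snap["bo"].copy()

    # -- forward / backward -------------------------------------------------

    def _encode(self, x: np.ndarray):
        """x: (B, t_in) -> (per-layer states, caches, alpha, context)."""
        seq = x.T[:, :, None]  # (T, B, 1)
        states_all, caches_all = [], []
        h0 = np.zeros((x.shape[0], self.units))
        inp = seq
        for layer in self.encoder:
            states, caches = layer.forward(inp, h0)
            states_all.append(states)
            caches_all.append(caches)
            inp = states
        alpha = np.exp(self.attn - self.attn.max())
        alpha /= alpha.sum()
        context = np.einsum("t,tbu->bu", alpha, states_all[-1])
        return states_all, caches_all, alpha, context

    def _decode_teacher(self, x, y, states_all, context):
        """Teacher-forced decoder pass.  Returns predictions and caches."""
        b = x.shape[0]
        y_prev = np.concatenate([x[:, -1:], y[:, :-1]], axis=1)  # (B, t_out)
        dec_in = np.concatenate(
            [y_prev.T[:, :, None], np.repeat(context[None], self.t_out, axis=0)],
            axis=2,
        )  # (t_out, B, 1+units)
        inp = dec_in
        dec_states_all, dec_caches_all = [], []
        for l, layer in enumerate(self.decoder):
            states, caches = layer.forward(inp, states_all[l][-1])
            dec_states_all.append(states)
            dec_caches_all.append(caches)
            inp = states
        top = dec_states_all[-1]  # (t_out, B, units)
        preds = (top @ self.wo)[:, :, 0].T + self.bo  # (B, t_out)
        return preds, dec_in, dec_states_all, dec_caches_all

    def _loss_and_grads(self, x: np.ndarray, y: np.ndarray) -> float:
        b = x.shape[0]
        for layer in self.encoder + self.decoder:
            layer.zero_grads()
        states_all, caches_all, alpha, context = self._encode(x)
        preds, dec_in, dec_states_all, dec_caches_all = self._decode_teacher(
            x, y, states_all, context
        )
        err = preds - y
        loss = float((err**2).mean())
        dpred = 2.0 * err / err.size  # (B, t_out)

        top = dec_states_all[-1]
        self._dwo = np.einsum("tbu,bt->u", top, dpred)[:, None]
        self._dbo = np.array([dpred.sum()])
        d_top = dpred.T[:, :, None] * self.wo[None, None, :, 0]  # (t_out,B,units)

        # decoder stack backward (top -> bottom)
        d_states = d_top
        d_h0 = [None] * self.n_layers
        for l in range(self.n_layers - 1, -1, -1):
            dxs, dh0 = self.decoder[l].backward(
                d_states, dec_caches_all[l], np.zeros((b, self.units))
            )
            d_h0[l] = dh0
            d_states = dxs  # becomes grad on layer below's output states
        d_dec_in = d_states  # (t_out, B, 1+units); [:, :, 0] is teacher input
        d_context = d_dec_in[:, :, 1:].sum(axis=0)  # (B, units)

        # attention backward
        enc_top = states_all[-1]  # (t_in, B, units)
        d_alpha = np.einsum("bu,tbu->t", d_context, enc_top)
        d_attn_pre = alpha * (d_alpha - float(alpha @ d_alpha))
        self._dattn = d_attn_pre
        d_enc_top = alpha[:, None, None] * d_context[None]  # (t_in, B, units)

        # encoder stack backward; decoder layer l's initial state is encoder
        # layer l's final state
        d_states = d_enc_top
        for l in range(self.n_layers - 1, -1, -1):
            dxs, _ = self.encoder[l].backward(
                d_states, caches_all[l], d_h0[l]
            )
            d_states = dxs if l > 0 else None
        return loss

    def _loss_only(self, x: np.ndarray, y: np.ndarray) -> float:
        states_all, _, _, context = self._encode(x)
        preds, *_ = self._decode_teacher(x, y, states_all, context)
        return float(((preds - y) ** 2).mean())

    def _rmsprop(self, rho: float = 0.9, eps: float = 1e-7) -> None:
        tensors = [(layer.params, layer.grads, k) for layer in self.encoder + self.decoder for k in layer.params]
        extra = [
            ("attn", self._dattn),
            ("wo", self._dwo),
            ("bo", self._dbo),
        ]
        idx = 0
        for params, grads, key in tensors:
            state = self._opt_state.setdefault(idx, np.zeros_like(params[key]))
            g = grads[key]
            state *= rho
            state += (1 - rho) * g * g
            params[key] -= self.lr * g / (np.sqrt(state) + eps)
            idx += 1
        for name, g in extra:
            cur = getattr(self, name)
            state = self._opt_state.setdefault(idx, np.zeros_like(cur))
            state *= rho
            state += (1 - rho) * g * g
            setattr(self, name, cur - self.lr * g / (np.sqrt(state) + eps))
            idx += 1

    def fit(self, x: np.ndarray, y: np.ndarray) -> "GRUForecaster":
        """Train on (N, t_in) inputs and (N, t_out) targets."""
        n = x.shape[0]
        order = self._rng.permutation(n)
        n_val = max(1, int(round(self.val_fraction * n))) if n >= 4 else 0
        val_idx, tr_idx = order[:n_val], order[n_val:]
        if tr_idx.size == 0:
            tr_idx, val_idx = order, order[:0]
        best_val, best_snap = np.inf, None
        for _ in range(self.epochs):
            self._loss_and_grads(x[tr_idx], y[tr_idx])
            self._rmsprop()
            if val_idx.size:
                val = self._loss_only(x[val_idx], y[val_idx])
                if val < best_val:
                    best_val, best_snap = val, self._snapshot()
        if best_snap is not None:
            self._restore(best_snap)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Closed-loop forecast: (N, t_in) -> (N, t_out)."""
        states_all, _, _, context = self._encode(x)
        h = [states_all[l][-1] for l in range(self.n_layers)]
        y_prev = x[:, -1]
        preds = []
        for _ in range(self.t_out):
            inp = np.concatenate([y_prev[:, None], context], axis=1)
            for l, layer in enumerate(self.decoder):
                h[l], _ = layer.step(inp, h[l])
                inp = h[l]
            y_prev = (h[-1] @ self.wo)[:, 0] + self.bo[0]
            preds.append(y_prev)
        return np.stack(preds, axis=1)


# ---------------------------------------------------------------------------
# Forecaster over gene series (scaling + model + evaluation)


@dataclass
class Forecaster:
    """A trained forecaster bound to its year windows and scaling rule."""

    model: GRUForecaster
    train_years: np.ndarray
    horizon_years: np.ndarray

    @staticmethod
    def _scale_params(train_vals: np.ndarray) -> tuple[float, float]:
        lo, hi = float(train_vals.min()), float(train_vals.max())
        if hi == lo:
            return lo, 1.0  # degenerate: maps the train window to all zeros
        return lo, hi - lo

    def _transform(self, vals: np.ndarray, lo: float, span: float) -> np.ndarray:
        return np.log1p(np.maximum((vals - lo) / span, 0.0))

    def _inverse(self, tvals: np.ndarray, lo: float, span: float) -> np.ndarray:
        return np.maximum(np.expm1(tvals) * span + lo, 0.0)

    def forecast(self, series: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
        """Forecast every gene and category; returns the evaluation table.

        Columns: gene, category, initial (cumulative value at the end of the
        training window), predicted/realised final values, fold_change
        (= (predicted+1)/(realised+1)), mase, plus the per-year vectors.
        """
        rows = []
        for gene, frame in series.items():
            for category in frame.columns:
                hist = frame.loc[self.train_years, category].to_numpy(float)
                real = frame.loc[self.horizon_years, category].to_numpy(float)
                lo, span = self._scale_params(hist)
                x = self._transform(hist, lo, span)[None, :]
                pred_t = self.model.predict(x)[0]
                pred = self._inverse(pred_t, lo, span)
                rows.append(
                    {
                        "gene": gene,
                        "category": category,
                        "initial": float(hist[-1]),
                        "predicted_final": float(pred[-1]),
                        "realised_final": float(real[-1]),
                        "fold_change": (pred[-1] + 1.0) / (real[-1] + 1.0),
                        "mase": mase(real, pred, hist),
                        "predicted": pred,
                        "realised": real,
                    }
                )
        return pd.DataFrame(rows)


def train_forecaster(
    series: Mapping[str, pd.DataFrame],
    train_end: int = 2013,
    horizon_end: int = 2019,
    units: int = 5,
    n_layers: int = 1,
    epochs: int = 300,
    lr: float = 5e-3,
    seed: int = 0,
    categories: Sequence[str] | None = None,
) -> Forecaster:
    """Train the GRU forecaster on all (gene, category) series pooled.

    Requires at least 10 series and a training window of at least 5 years.
    Per-series min-max scaling is fitted on the training window; constant
    (all-equal) training windows scale to all zeros and are excluded from
    the training pool with a warning.  Deterministic given ``seed``.
    """
    frames = list(series.values())
    if not frames:
        raise ValueError("no series to train on")
    years = frames[0].index.to_numpy()
    train_years = years[(years <= train_end)]
    horizon_years = years[(years > train_end) & (years <= horizon_end)]
    if train_years.size < 5:
        raise ValueError("training window shorter than 5 years")
    if horizon_years.size == 0:
        raise ValueError("empty forecast horizon")

    xs, ys = [], []
    n_degenerate = 0
    for frame in frames:
        cols = categories if categories is not None else frame.columns
        for category in cols:
            hist = frame.loc[train_years, category].to_numpy(float)
            future = frame.loc[horizon_years, category].to_numpy(float)
            lo, hi = float(hist.min()), float(hist.max())
            if hi == lo:
                n_degenerate += 1
                continue
            span = hi - lo
            xs.append(np.log1p((hist - lo) / span))
            ys.append(np.log1p(np.maximum((future - lo) / span, 0.0)))
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} constant training series scaled to zeros and "
            "excluded from the training loss",
            stacklevel=2,
        )
    if len(xs) < 10:
        raise ValueError("fewer than 10 usable series")
    x = np.stack(xs)
    y = np.stack(ys)
    model = GRUForecaster(
        t_in=train_years.size,
        t_out=horizon_years.size,
        units=units,
        n_layers=n_layers,
        lr=lr,
        epochs=epochs,
        seed=seed,
    )
    model.fit(x, y)
    return Forecaster(model=model, train_years=train_years, horizon_years=horizon_years)


# ---------------------------------------------------------------------------
# MASE


def mase(actual: Sequence[float], predicted: Sequence[float], history: Sequence[float]) -> float:
    """Mean absolute scaled error against the repeat-last-value naive model.

    Returns +inf when the naive error is zero but the forecast errs, and 0
    when both are exact.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    history = np.asarray(history, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have the same length")
    if actual.size == 0:
        raise ValueError("empty horizon")
    if history.size == 0:
        raise ValueError("empty history")
    err = float(np.abs(actual - predicted).mean())
    naive = float(np.abs(actual - history[-1]).mean())
    if naive == 0.0:
        return 0.0 if err == 0.0 else float("inf")
    return err / naive


# ---------------------------------------------------------------------------
# Trendiness


def _right_tail(points: np.ndarray, x0: float, bandwidth: float) -> float:
    """Right-tail mass of a Gaussian KDE from x0 to +inf (closed form)."""
    return float(norm.cdf((points - x0) / bandwidth).mean())


def compute_trendiness(
    results: pd.DataFrame,
    n_bins: int = 5,
    bandwidth: float = 0.1,
) -> pd.DataFrame:
    """Right-tail trendiness per gene and category within volume bins.

    ``results`` is the forecast table (gene, category, initial,
    fold_change).  Within each category, genes are binned by the percentiles
    (20, 40, ..., 100) of ``initial``; a Gaussian KDE (bandwidth 0.1) is
    fitted to the bin's log2 fold changes, and trendiness(g) = P(F >= f_g)
    under that density.  Bins with fewer than 2 genes are merged into their
    lower neighbour with a warning.  Requires at least ``n_bins`` genes with
    defined fold changes per category.
    """
    out_rows = []
    for category, group in results.groupby("category", sort=False):
        group = group.dropna(subset=["fold_change"])
        if len(group) < n_bins:
            raise ValueError(
                f"need at least {n_bins} genes with defined fold changes "
                f"in category {category!r}"
            )
        initial = group["initial"].to_numpy(float)
        logf = np.log2(group["fold_change"].to_numpy(float))
        quantiles = np.quantile(initial, np.linspace(0, 1, n_bins + 1)[1:])
        bins = np.searchsorted(quantiles[:-1], initial, side="left")

        # merge undersized bins into their lower (or upper) neighbour
        merged = True
        while merged:
            merged = False
            ids, counts = np.unique(bins, return_counts=True)
            for bid, cnt in zip(ids, counts):
                if cnt < 2 and len(ids) > 1:
                    neighbours = ids[ids != bid]
                    target = neighbours[neighbours < bid].max() if (neighbours < bid).any() else neighbours.min()
                    warnings.warn(
                        f"bin {int(bid)} in category {category!r} has {int(cnt)} "
                        f"gene(s); merged into bin {int(target)}",
                        stacklevel=2,
                    )
                    bins[bins == bid] = target
                    merged = True
                    break

        for bid in np.unique(bins):
            mask = bins == bid
            points = logf[mask]
            for gene, f, init in zip(
                group.loc[mask, "gene"], logf[mask], initial[mask]
            ):
                out_rows.append(
                    {
                        "gene": gene,
                        "category": category,
                        "bin": int(bid) + 1,
                        "initial": float(init),
                        "log2_fold_change": float(f),
                        "trendiness": _right_tail(points, float(f), bandwidth),
                    }
                )
    return pd.DataFrame(out_rows)
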