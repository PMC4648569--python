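"""Numba kernels for the daily movement/oviposition loop.

A female's day is a sequence of uniform-random-direction flight steps whose
length depends on whether her current cell holds an available host (short
oviposition-search steps) or on the aridity class otherwise.  Landing on an
available host that her genotype accepts yields an egg with a fixed
probability; the day ends when her cumulative flight distance reaches the
sampled daily budget or she has laid her whole daily egg load.  The season
kernel iterates this over 54 days for a whole cohort, recording every egg
with its cell, day, sex and transmitted alleles.

Randomness uses numba's internal np.random state, seeded once per kernel
entry point with a seed derived from the caller's Generator, so runs are
reproducible for a fixed configuration seed.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi


@njit(cache=True)
def _reflect(v, hi):
    """Fold a coordinate back into [0, hi) by specular reflection."""
    period = 2.0 * hi
    v = v % period
    if v < 0.0:
        v += period
    if v >= hi:
        v = period - v
    if v >= hi:  # v landed exactly on the fold point
        v = hi * (1.0 - 1e-12)
    return v


@njit(cache=True)
def fly_day(x, y, avail, is_thl, aridity, accepts, fa1, fa2, mom_z,
            egg_load, budget, ovi_prob,
            step_wet_m, step_int_m, step_dry_m, step_host_m, cell,
            egg_r, egg_c, egg_sex, egg_z1, egg_z2, egg_thl, idx0):
    """One female-day.  Returns (x, y, n_eggs_laid, distance_flown).

    Eggs are appended to the shared buffers starting at index ``idx0``:
    egg_z1 is the paternally transmitted allele (a coin flip between the
    father's two alleles), egg_z2 the mother's allele (meaningful for sons).
    """
    n_rows, n_cols = aridity.shape
    width = n_cols * cell
    height = n_rows * cell
    laid = 0
    dist = 0.0
    while True:
        r = int(y / cell)
        c = int(x / cell)
        if r >= n_rows:
            r = n_rows - 1
        if c >= n_cols:
            c = n_cols - 1
        if avail[r, c]:
            step = step_host_m
        else:
            a = aridity[r, c]
            if a == 0:
                step = step_wet_m
            elif a == 1:
                step = step_int_m
            else:
                step = step_dry_m
        theta = TWO_PI * np.random.random()
        x = _reflect(x + step * math.cos(theta), width)
        y = _reflect(y + step * math.sin(theta), height)
        dist += step
        r = int(y / cell)
        c = int(x / cell)
        if r >= n_rows:
            r = n_rows - 1
        if c >= n_cols:
            c = n_cols - 1
        if avail[r, c] and (not is_thl[r, c] or accepts):
            if np.random.random() < ovi_prob:
                k = idx0 + laid
                egg_r[k] = r
                egg_c[k] = c
                egg_sex[k] = 1 if np.random.random() < 0.5 else 0
                egg_z1[k] = fa1 if np.random.random() < 0.5 else fa2
                egg_z2[k] = mom_z
                egg_thl[k] = is_thl[r, c]
                laid += 1
                if laid >= egg_load:
                    break
        if dist >= budget:
            break
    return x, y, laid, dist


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def run_season(avail3, is_thl, aridity, emergence, lifespan, budgets,
               load_table, x, y, accepts, fa1, fa2, mom_z, has_mate,
               ovi_prob, step_wet_m, step_int_m, step_dry_m, step_host_m,
               cell, season_length, seed,
               egg_r, egg_c, egg_day, egg_sex, egg_z1, egg_z2, egg_thl):
    """A full 54-day flight season for one cohort.  Returns total eggs laid.

    Females activate on their scheduled emergence day, fly daily with fresh
    flight and egg budgets, and are removed once their lifespan has elapsed.
    Unmated females (no surviving male pool) never fly.
    """
    np.random.seed(seed)
    n = x.shape[0]
    idx = 0
    for day in range(1, season_length + 1):
        tri = (day - 1) * 3 // season_length
        avail = avail3[tri]
        for i in range(n):
            if not has_mate[i]:
                continue
            if day < emergence[i]:
                continue
            age = day - emergence[i] + 1
            if age > lifespan[i]:
                continue
            load_age = age if age < load_table.shape[0] else load_table.shape[0] - 1
            egg_load = load_table[load_age]
            if egg_load <= 0:
                continue
            xi, yi, laid, _ = fly_day(
                x[i], y[i], avail, is_thl, aridity, accepts[i],
                fa1[i], fa2[i], mom_z[i], egg_load, budgets[i, day - 1],
                ovi_prob, step_wet_m, step_int_m, step_dry_m, step_host_m,
                cell, egg_r, egg_c, egg_sex, egg_z1, egg_z2, egg_thl, idx)
            x[i] = xi
            y[i] = yi
            for k in range(idx, idx + laid):
                egg_day[k] = day
            idx += laid
    return idx
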