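"""Independent hand-stepped oracle for the 3-SSMU toy world.

Implements the seasonal ledger with plain scalar loops and explicit
arithmetic — no shared code with the package's dynamics engine — so it can
serve as an independent expectation for the vectorized implementation.
"""
import math

# --- toy definition, restated by hand -------------------------------------
AREAS = {1: 1.0e10, 2: 2.0e10, 3: 1.0e10}
B0 = {1: 300_000.0, 2: 400_000.0, 3: 20_000.0}          # tonnes
MAX_REC = {s: B0[s] * (math.exp(0.8) - 1.0) for s in B0}  # steady state
MAX_REC[3] *= 0.3                                         # low-recruitment sink
M_KRILL = 0.4                                             # per season
GROUPS = ("penguins", "seals")
N0 = {("penguins", 1): 2.0e4, ("penguins", 2): 1.5e4, ("seals", 3): 1.2e3}
DEMAND = {("penguins", "summer"): 0.08, ("penguins", "winter"): 0.04,
          ("seals", "summer"): 0.8, ("seals", "winter"): 0.4}
M_PRED = {"penguins": 0.10, "seals": 0.12}
H_SHAPE = 0.2
FORAGING = {
    ("summer", "penguins", 1): {1: 0.70, 2: 0.20, 3: 0.10},
    ("summer", "penguins", 2): {1: 0.15, 2: 0.75, 3: 0.10},
    ("summer", "seals", 3): {1: 0.10, 2: 0.20, 3: 0.70},
    ("winter", "penguins", 1): {1: 0.50, 2: 0.30, 3: 0.20},
    ("winter", "penguins", 2): {1: 0.20, 2: 0.60, 3: 0.20},
    ("winter", "seals", 3): {1: 0.20, 2: 0.30, 3: 0.50},
}
CATCH_ANNUAL = {1: 0.2, 2: 0.2, 3: 0.6}
CATCH_SEASONAL = {1: {"summer": 0.7, "winter": 0.3},
                  2: {"summer": 0.6, "winter": 0.4},
                  3: {"summer": 0.5, "winter": 0.5}}
HARVEST_RATE = 0.093


def run_toy_oracle(n_years=2):
    """Hand-stepped baseline run; returns rows
    (year, season, variable, group, ssmu, value)."""
    limit = sum(B0.values()) * HARVEST_RATE
    alloc = {(s, se): limit * CATCH_ANNUAL[s] * CATCH_SEASONAL[s][se]
             for s in B0 for se in ("summer", "winter")}
    B = dict(B0)
    N = dict(N0)
    rows = []
    for (g, s), v in N.items():
        rows.append((0, "initial", "predators", g, s, v))
    for year in range(n_years):
        x_summer = {}
        for season in ("summer", "winter"):
            # 1. recruitment (summer only), 2. availability
            avail = {}
            for s in B0:
                rec = MAX_REC[s] if season == "summer" else 0.0
                avail[s] = B[s] + rec
            # 3. demand and proportional competition
            demand = {s: alloc[(s, season)] for s in B0}
            for (se, g, i), row in FORAGING.items():
                if se != season:
                    continue
                total = N[(g, i)] * DEMAND[(g, season)]
                for j, p in row.items():
                    demand[j] += total * p
            scale = {s: (1.0 if demand[s] <= avail[s] else avail[s] / demand[s])
                     for s in B0}
            for s in B0:
                consumed = demand[s] * scale[s]
                catch = alloc[(s, season)] * scale[s]
                # 4. mortality (no movement in the toy)
                B[s] = (avail[s] - consumed) * math.exp(-M_KRILL)
                rows.append((year, season, "krill", "", s, B[s]))
                rows.append((year, season, "catch", "", s, catch))
            if season == "summer":
                for (g, i) in N:
                    x = sum(p * scale[j]
                            for j, p in FORAGING[("summer", g, i)].items())
                    x_summer[(g, i)] = x
        # 6. annual predator update from summer realized fraction
        for (g, i) in N:
            x = x_summer[(g, i)]
            phi = x * (1.0 + H_SHAPE) / (x + H_SHAPE)  # hyperstable
            S = math.exp(-M_PRED[g])
            N[(g, i)] = N[(g, i)] * (S + (1.0 - S) * phi)
            rows.append((year, "annual", "predators", g, i, N[(g, i)]))
    return rows


if __name__ == "__main__":
    import csv, sys
    w = csv.writer(sys.stdout)
    w.writerow(["year", "season", "variable", "group", "ssmu", "value"])
    for r in run_toy_oracle():
        w.writerow([r[0], r[1], r[2], r[3], r[4], repr(r[5])])
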