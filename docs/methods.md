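# Methods

## The scheduling problem

A combinatorial liquid-transfer task moves volumes from wells of a source
plate to wells of a destination plate with an 8-channel pipette whose tips
are individually addressable along the short plate axis.  The task is a
matrix **T** of shape (n_src, n_dst) whose non-zero entry T[a, b] = v is one
*job*: aspirate v uL from source well a, dispense into destination well b.
Execution proceeds in *cycles* of at most 8 jobs — aspirate all, move the
arm to the destination carrier, dispense all, wash — with tips assigned in
ascending order within a cycle.  Wells are numbered 1-based, column-major
(A1 = 1, B1 = 2, ...).

Two jobs whose wells sit in the same column with the second exactly one
adjacency stride below the first can be served by neighbouring tips in a
single lower–transfer–raise–move stroke.  The stride reflects well pitch:
1 for 12-, 24- and 96-well plates, 2 for 384, 4 for 1536.  The relation is
directional (tips are assigned in ascending order, so within a column row 3
pairs with row 4, not with row 2), and a well is never "adjacent" to
itself: two tips cannot occupy one well, so two jobs sharing a well always
cost a second stroke.  This last case is a package decision — the physical
argument fixes it, and no alternative is coherent.

## Cost model

Well adjacency is encoded as a binary directional distance matrix D per
plate and lifted to job level via the task's incidence matrices.  The
routing cost of executing job j directly after job i within a cycle is

    D'[i, j] = dbar_src[i, j] * (t134_src + v_j / q_src)
             + dbar_dst[i, j] * (t134_dst + v_j / q_dst)

where t134 aggregates tip lowering, raising and arm movement for one stroke
(default 1 s per plate side), q is the aspiration or dispense rate (default
100 uL/s), and v_j is the successor's volume, so v_j/q is its rate-limited
transfer time.  When j is adjacent to i on a plate, the tips act
simultaneously there and that plate side contributes nothing.  A dummy job
0 with zero volume and zero distance to and from every job represents the
start and end of each cycle; row and column 0 of D' are therefore zero.

The adjacency gate multiplies the *whole* unit-action cost, including the
volume term.  An additive placement (gate only the t134 term, always charge
v/q) is available as `variant="additive"` for sensitivity analyses; it is
not the default because adjacent consecutive jobs are genuinely free on
hardware, and because it would give the depot non-zero distances.

Arm travel between positions within one labware is ignored (well under a
second per move on common platforms, far below the stroke and transfer
times), as is the fixed source-to-destination transit, which is determined
by the cycle count and not by the ordering.

The *computed execution time* of a work list is the sum of D' over
consecutive within-cycle job pairs.  Minimising it over all orderings and
cycle assignments is a capacitated vehicle routing problem: jobs are
locations, cycles are vehicles of capacity 8 (tip count; configurable), and
the dummy job is the depot.  Because depot edges are free, a plan is fully
described by a flat job sequence whose cycles are the consecutive blocks of
8; arcs that cross a block boundary cost nothing.

## Schedulers

* **row-major** — the control: jobs in task-matrix scan order, ascending
  (source well, destination well).
* **LAP (long-axis prioritised)** — repeated passes over the wells of the
  plate with more wells in column-major order, taking one job per well per
  pass until all jobs are consumed; each pass visits strictly increasing
  well positions on that plate, maximising tip-adjacent runs there.  Jobs
  within a well are consumed in ascending order of their other-plate
  position; with equal-sized plates the destination is the sampled axis.
  Both tie rules are open choices and a seeded tie shuffle exists for
  sensitivity runs.
* **greedy** — one global nearest-neighbour chain on D': seeded uniform
  random start, then always the closest unassigned job, ties broken
  uniformly at random.
* **cvrp** — the routing optimiser, described next.

## The routing backend

The built-in backend optimises the flat sequence directly, which enforces
the capacity and cycle-count constraints by construction.

*Construction.*  Cheapest-arc chaining: the first block opens with the
globally cheapest arc, later blocks with the unvisited job whose cheapest
outgoing arc is smallest, and blocks fill nearest-neighbour (ties to the
lowest job index).  A second deterministic start, the LAP pass ordering, is
also evaluated and the cheaper of the two seeds the search — warm-starting
from a known feasible plan is standard routing practice and matters on
structured tasks whose global pass structure a greedy chain cannot recover.

*Local search.*  Seeded first-improvement search over four move families:
a targeted move that pulls one of a job's k = 12 nearest successors into
the position after it (as an in-block relocation, an equal-offset tail
exchange, or a plain position swap, depending on where the successor
sits); random position swaps; random equal-offset block-tail exchanges
(2-opt* between cycles — with fixed blocks both tails start at the same
within-block offset and have equal length, so only the two entering arcs
change); and short segment reversals (2-opt, re-evaluated over the window
because the distance matrix is asymmetric).

*Metaheuristic.*  Guided local search: when the search stalls, the arcs of
the current plan with the highest utility cost/(1 + penalty) receive a
penalty increment of lambda = 0.1 x (construction cost)/m on an augmented
copy of the distance matrix; descent continues on the augmented costs while
the incumbent is tracked on the true costs.  The search terminates early
only when every paid arc of the current plan is free, i.e. the plan is
provably optimal (the objective is non-negative).

*Budget.*  The budget is a count of move evaluations, so runs are
reproducible and machine-independent, and the best-so-far plan with a
larger budget is never worse than with a smaller one (anytime
monotonicity).  The default of 400,000 evaluations corresponds to roughly
5–20 s of single-core search at benchmark sizes and is the package's
stand-in for wall-clock solver budgets of that order; an optional
wall-clock cap can be layered on top for interactive use.  An
`integer_distances` view (scale 1000, rounded) exists for integer-only
backends; reported times are always unscaled float sums.

*Oracle.*  For m <= 10 jobs an exhaustive oracle enumerates every
permutation (vectorised, chunked) and, when two cycles are required, every
admissible cycle break, independently of the heuristic code paths.  It is
a test fixture, not a scheduler: exact solving is intractable at realistic
sizes.

## Event simulator

The computed time is a proxy; to validate it without vendor software the
package ships an event-level simulator.  Per cycle, the aspiration pass
splits the cycle's jobs into maximal runs of consecutive tip-adjacent
source wells; each run is one stroke costing t1 + max(v)/q_src + t3 + t4
(tips transfer simultaneously, so the slowest volume in the run paces it).
The dispense pass is analogous on the destination plate; each cycle adds
one arm transit and one wash.  Defaults split the stroke aggregate as
t1 = 0.4, t3 = 0.4, t4 = 0.2 (so t1+t3+t4 equals the cost model's t134 of
1 s) with wash and transit at zero, letting proxy and simulator be compared
cleanly; a `TECAN_LIKE` preset carries illustrative per-cycle overheads.

The proxy and the simulator deliberately differ in volume accounting: the
proxy charges the successor's v/q on non-adjacent transitions, the
simulator charges each run's maximum.  They are therefore compared by
correlation (Pearson r > 0.9 over random tasks across 12/24/96-well
formats in the test suite), not by identity; with equal volumes the two
rank single-cycle schedules identically.

## Synthetic data

Two generators drive all benchmarks, so every study condition is explicit:

* **Random tasks** — exactly n unique (source, destination) cells drawn
  uniformly without replacement, volumes i.i.d. uniform on [1, 100] uL.
  The distribution is continuous; whether volumes should be integers is
  underdetermined, so an integer flag exists.  These tasks have no spatial
  structure, which favours no scheduler a priori.
* **Campaign tasks** — a stand-in for adaptive screening campaigns (no real
  campaign files ship with the package; `run_campaign` loads external
  work-list CSVs when they are available).  Round 0 is a diagonal control
  task with the first 8 task-matrix rows empty; round 1 draws 4 uniform
  source components for each active destination well; later rounds skew
  source usage with Zipf-like weights (exponent 1.2) over a fixed random
  source ranking, emulating how an optimiser increasingly favours certain
  stock solutions.  Destination wells 1–8 stay free for controls.  The
  component count (4), reserved rows (8) and round count (9) mirror a
  96-well blending campaign of moderate size; the Zipf exponent is a
  package choice of "visibly skewed but not degenerate".

Neither generator models liquid classes, failed transfers, deck layout or
multi-plate campaigns, so passing benchmarks demonstrate ordering quality
under the stated cost model, not end-to-end wall-clock fidelity on any
particular instrument.

## Benchmark designs and problem sizes

* Method sweep: per plate combination, task sizes at 1x–10x the
  destination well count, 3 random tasks per size, every scheduler on every
  task; summarised as mean +/- sd per cell.  The package's headline
  reproduction runs the dense-destination combinations 96->96 and 24->96 at
  1x–5x — sizes where the full design's qualitative picture is already
  stable — and reports the mean per-cell percent reduction of the routing
  scheduler against row-major and LAP.
* Budget sweep: cost versus solver budget on 2000-transfer 96->96 tasks
  (2–70 s in the full design); the reproducible variant uses
  move-evaluation budgets at m = 200, where the mean cost is non-increasing
  and plateaus.
* Campaign replay: every iteration scheduled by every method; per-iteration
  and summed computed (and simulated) times.

All sub-seeds derive from one base seed through `numpy` seed sequences;
reports reproduce bit-for-bit apart from recorded wall-clock solve times.

## Numerical choices and edge cases

* Strict-improvement threshold 1e-12 in the search; costs are sums of a few
  thousand O(1)-magnitude terms, so this is far below any real difference.
* Ties in construction and argmin scans break to the lowest job index;
  greedy breaks ties uniformly at random by design (seeded).
* Empty tasks yield empty work lists with zero cost; a single job costs
  zero (it enters from the depot).
* Duplicate (source, destination) rows in input CSVs are rejected — the
  matrix representation cannot encode them — unless an explicit merge flag
  sums them.
* Dense D' above 15,000 jobs triggers a memory warning rather than a hard
  failure (about 1.8 GB at that size).

## Known limitations

* The simulator is an open stand-in, not a vendor emulator; absolute
  minute-scale agreement with proprietary simulators is out of scope.
* Multi-aspiration/multi-dispense with tip reuse is excluded (the
  cross-contamination risk makes it protocol-specific); sequence-constrained
  protocols can be handled by partitioning the task matrix and scheduling
  the parts independently.
* 96-channel heads and acoustic dispensers follow different mechanics and
  are not covered.
* The backend is a heuristic: it guarantees feasibility and never returns
  worse than its construction, but not optimality beyond the tiny exact
  range.
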