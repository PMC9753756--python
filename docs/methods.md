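# Methods

## The model

`ringmelt` simulates melts of unknotted, mutually non-concatenated ring
polymers (and reference melts of open linear chains) as *elastic lattice
polymers* on the face-centered-cubic lattice, evolved by kinetic Monte
Carlo, and analyzes their conformations through the entanglement-unit
system, minimal spanning surfaces, and threading statistics.

### Lattice and chains

fcc sites are embedded as the integer triples `(x, y, z)` with even
coordinate sum; the nearest-neighbor bond `a = sqrt(2)` embedding units is
the unit of length in every reported observable. A chain is an ordered
list of `N` monomers; consecutive monomers sit on nearest-neighbor sites
(an *effective* bond of length `a`) or on the same site (a *stored-length*
unit, bond length 0). At most two consecutive monomers may share a site,
and non-consecutive monomers never do (excluded volume). Rings close
cyclically (`N+1 = 1`). Stored length makes the chains longitudinally
elastic: slack diffuses along the contour and realizes reptation-like mass
transport without violating excluded volume.

### Bending energy

The bending Hamiltonian is

    E = -kappa_bend * sum_{i=1..N} cos(theta_i)

with one term per monomer; `theta_i` is the angle between the nearest
effective bonds on the two sides of monomer `i`, skipping zero-length
bonds. Both monomers of a stored-length pair therefore see the same
flanking bond pair, so the angle across a stored unit carries twice the
Boltzmann weight of an ordinary one. Keeping the term count fixed at `N`
makes stored length energetically neutral inside straight chain sections;
together with the bookkeeping above, equilibrium slack *grows* with
stiffness, which is what the model's reference calibration shows
(`<b>/a = 0.731, 0.696, 0.669` at `kappa_bend = 0, 1, 2`). The per-monomer
convention was selected against the alternatives (a single term per
consecutive effective-bond pair; free hinges at stored units) because only
it reproduces, with no free parameter, the direction and the approximate
magnitude of the calibrated `<b>(kappa)` and `<cos theta>(kappa)` columns
simultaneously; see "Known limitations" for the residuals.

For an ideal (phantom) chain the stationary distribution of the angle
between *adjacent* effective bonds is exactly the discrete Boltzmann form
`P(cos) ~ Omega(cos) exp(kappa cos)` with lattice degeneracies
`Omega = 1, 4, 2, 4, 1` over `cos theta = 1, 1/2, 0, -1/2, -1` (bond
angles 0, 60, 90, 120, 180 degrees; the lattice geometry fixes these
values). This is a transfer-matrix identity (the lattice point group acts
transitively on bond orientations, making the uniform orientation vector
the Perron eigenvector) and is used as the detailed-balance oracle of the
engine.

### Kinetic Monte Carlo

One elementary attempt: a uniformly random monomer, a uniformly random one
of the 12 neighbor displacements. The move is applied iff (i) both
adjacent bonds keep length 0 or `a`, (ii) the destination site is empty or
holds exactly one monomer which is a chain neighbor of the mover, and
(iii) a Metropolis test on the bending-energy change passes. The energy
difference is evaluated from a five-monomer window around the mover, which
is exact because a move changes only the mover's two bonds and zero bonds
are isolated (this is verified against a whole-chain oracle in the tests).
The configuration measure is uniform over valid states modulated by the
bending Boltzmann factor (stored-length weight 1). One kMC time unit
tau_MC is one attempted move per monomer. The inner loop is numba-compiled
(~5-10 million attempts per second on one core) and a run is bit-for-bit
reproducible from its seed. No explicit non-crossing check is performed:
the bond-length and occupancy constraints conserve topology, which the
tests *monitor* through Gauss linking matrices along trajectories.

### Melt construction

Melts are built at occupancy 1.25 monomers per fcc site, i.e.
`rho a^3 = 1.25 sqrt(2) = 1.77` (the fcc site volume is `a^3/sqrt 2`).
Each ring is laid out as a flat "racetrack" loop (two zigzag legs joined
by end turns) confined to one lattice plane; distinct rings fill disjoint
slabs, so the initial state is manifestly unknotted and pairwise unlinked,
and linear melts reuse the same layout without closure. Stored-length
units are distributed to cover ~60% of each loop's sites, which starts the
melt on the slack-rich side of equilibrium: free volume exists everywhere
and the system relaxes from the mobile side (starting from dense, slack-
poor states can jam kinetically). Because all box edges must be even, the
fcc site count is a multiple of four and very small melts cannot always
reach the requested occupancy within 2%; the builder then warns and uses
the closest achievable box.

## Entanglement units

From an equilibrated *linear* melt the package measures the mean bond
length `<b>` (the fraction of non-zero bonds) and the Kuhn length `l_K` as
the plateau of `<R^2(l)>/l` fitted on the contour window `l` in
[150, 200] a (configurable; flagged unreliable when the ratio still drifts
by >10% across the window). The entanglement length follows from the
Uchida-Grest-Everaers crossover

    L_e / l_K = (0.06 n_K)^-2 + (0.06 n_K)^-(2/5),   n_K = rho <b> l_K^2,

whose loose (exponent 2) and tight (exponent 2/5) limits bracket the
packing argument; the numerical coefficient 0.06 is validated in the tests
against all three calibrated `(l_K, n_K) -> L_e` triples (agreement
< 0.1%). The tube diameter is the ideal-strand gyration radius
`d_T = sqrt(l_K L_e / 6)`, `N_e = L_e/<b>`, and the entanglement time
tau_e solves `g1(tau_e) = d_T^2` on a measured monomer MSD curve by
log-log interpolation. Chain and subchain contours convert to
entanglement counts `Z = L/L_e`, `z = l/L_e`.

## Static observables

Gyration radius/tensor are standard; the squared magnetic radius is
`R_m^2 = |A|/pi` with `A = 1/2 sum r_i x r_{i+1}` the oriented ring area -
the normalization is pinned by the circle limit (a planar circle of radius
R returns `R_m = R`), and a symmetric figure-eight returns 0. Bond
correlations `c(l)` correlate effective-bond orientations at monomer
separation `n` (`l = n <b>`); the exactly double-folded filament of
contour `2 L_e` obeys `c(z) = (1 - 3z/2)/(1 - z/2)` for `0 < z < 1` and
`c = -1` for `1 <= z < 2` (this closed form holds for the *open* hairpin;
a closed double-folded loop would give `1 - 2z`). Ring contact
probabilities use the minimum-image distance with contact radius one
lattice unit and the shorter ring arc as contour separation; finite-ring
effects are absorbed by `zeta = z(1 - z/Z)`. Power laws are fitted by
log-log least squares with a minimum half-decade span.

## Minimal surfaces and threading

Each ring's spanning disc starts as the center-of-mass fan over its
effective contour (stored-length segments subtend no area), is refined by
edge-midpoint subdivision (new boundary midpoints stay on the contour),
and evolves under surface tension: umbrella (neighbor-average) smoothing
steps accepted only when the area does not increase, with an
area-gradient fallback and occasional area-reducing edge flips; the flow
stops when the relative area change over 30 accepted steps is below 0.1%.
Collapsed zero-area slivers are pruned (they carry no area and cannot be
pierced transversally). On a discretized circle the flow recovers the disc
area to better than 0.1%.

Piercings are transversal intersections of another ring's effective bonds
with the surface (vectorized segment-triangle tests; a deterministic
sub-lattice offset resolves degenerate touches), signed by the bond
orientation against the surface normal, taken in the partner's nearest
periodic image. Crossings sorted along the threader's contour must
alternate in sign; near-tangent same-sign pairs are removed (logged), and
a remaining odd count excludes the pair. Arcs between consecutive
crossings are threading segments with length `L_t`; `L_sep` is the
minority-side total, `Q = L_sep/(L - L_sep)` in [0, 1]; segments with
`L_t < L_e` are *shallow* and can be filtered out of every statistic. The
deep-threading network joins rings linked by at least one segment with
`L_t > L_e`; its largest-component fraction diagnoses percolation.
Averaging populations: `n_t` per ring, `Q` and `n_p` per ordered pair with
at least one retained segment, `d` (piercing-pair midpoint distance) per
segment.

## Dynamics

g1/g2/g3 are time- and ensemble-averaged over evenly spaced unwrapped
snapshots with logarithmic lag grids; with pinning, averages run over
unpinned rings. A run counts as structurally relaxed when g2 is flat over
its last lag decade (log-log slope < 0.05) within 20% of `2 <R_g^2>`.
Reference curves implement the tree-like relaxation picture with tube
dilation parameter theta: `rho_eff = rho(1-theta) + nu*theta`,
`tau_r = tau_e Z^(2+rho_eff)`, intermediate g1 exponent
`2 nu/(2+rho_eff)` (= 6/23 ~ 0.26 undilated, 2/7 ~ 0.29 fully dilated),
and `D ~ N^(2 nu - 2 - rho_eff)` (-17/9 and -5/3 in the two limits). The
smooth three-regime curve shapes use the multiplicative crossover
`x^a (1+x)^(b-a) (1+x/x_r)^(1-b)`; the limiting exponents are the model's,
the O(1) crossover coefficients are this package's interpolation choice
and are not fitted to data. theta is a pure model parameter, never fitted.

Random-pinning experiments freeze `floor(f_p M)` rings of an equilibrated
melt and record g3 of the rest; a late-time plateau below a threshold
fraction of `2<R_g^2>` flags freezing. Pinning must be applied to an
equilibrated melt: on an unrelaxed one, construction transients dominate
g3 and can mask the slowdown.

## Problem sizes in the test suite and acceptance script

Tests and the acceptance script use scaled-down study conditions chosen so
each stage actually reaches the regime it claims to probe: local/angle
observables use melts of 1 600-16 000 monomers at the reference density;
threading and pinning checks use matched-Z melts (Z ~ 1.5-3) equilibrated
for several tau_e; the equilibrium-angle reproduction uses linear chains
of N = 100 and rings small enough (Z ~ 3) that the structural relaxation
time `tau_r ~ tau_e Z^2.56` fits the run length - rings of N = 100 at
kappa_bend = 2 (tau_r ~ 5x10^6 sweeps) provably do not relax on desk
scales and are not used for equilibrium claims.

## Known limitations

* The microscopic stored-length/bending bookkeeping of the original
  lattice model is not fully recoverable from published material. The
  per-monomer convention adopted here reproduces the calibrated `<b>`
  column (0.732 vs 0.731 at kappa=0 on 16k monomers), the acceptance-rate
  column to ~10%, and `<cos theta>` at kappa=1 (0.47 vs 0.476), but
  underestimates `<cos theta>` at kappa=0 (0.10-0.12 vs 0.187) and
  overshoots at kappa=2 (linear: ~0.70 vs 0.670). These residuals are
  stable against box size and run length and should be read as a model
  variant difference, not statistical error.
* Ring melts deep in the stiff/entangled regime equilibrate at
  `tau_r ~ tau_e Z^(2+rho)`; quantities that require full structural
  relaxation (large-Z ring sizes, deep-threading abundances, Kuhn-length
  plateaus at the published window) are only reached directionally at desk
  scale. The synthetic melts also start from flat, layered loops, so
  threading statistics need several tau_e of equilibration before any
  inter-ring piercing exists at all.
* Linking numbers and piercing images use the nearest periodic image;
  rings spanning more than half the box trigger warnings and their
  topology assessment is convention-dependent.
* The engine performs single-monomer moves only; connectivity-altering or
  collective moves, shear, and cluster-parallel decomposition are out of
  scope.
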