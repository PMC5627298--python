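# dictywalk

Discrete modelling of amoeboid locomotion and chemotaxis by tracking
pseudopod growth direction.

Crawling amoebae such as *Dictyostelium discoideum* move by extending
pseudopodia — transient actin-driven protrusions — and the sequence of
growth directions is highly structured: an existing pseudopod usually
*splits* about ±60° to its left or right (with left/right alternation
about three times more common than two same-handed splits in a row),
while occasionally a *de novo* pseudopod appears at the cell rear in an
essentially random direction.  `dictywalk` implements a minimal discrete
model of this process for people studying cell motility statistics:
the pseudopod direction lives on six lattice directions
θₙ = (n−1)π/3, and because the next direction depends on the current
*and* the previous one, the direction sequence is a second-order Markov
chain.  Tracking the pair Xₜ = (θₜ₋₁, θₜ) restores the Markov property
on a 30-state space with a sparse 30×30 transition matrix P⁰ built from
three parameters:

* `p` — probability of a de novo pseudopod per step (default 1/7, each
  of the three rear directions getting p/3),
* `alpha` / `beta` — same-handed vs alternating split weights
  (defaults 0.25 / 0.75, so alternating:consecutive = 3).

Its stationary distribution ω₀ (the left unit eigenvector, ω₀(𝕀−P⁰)=0)
has the closed form (1−p)/12 on adjacent-direction pairs and p/18 on
wide-turn pairs, independent of α and β — the chain's one-step memory
vanishes in the long run and every direction is equally likely (1/6).

A chemoattractant gradient (direction ĝ, default +y) adds a linear bias
P = P⁰ + ε ĝ·n̂ⱼ to every allowed target direction n̂ⱼ except the
back-step, with coupling coefficient ε = γ L |∇C| / C (cell size L,
local concentration C).  The biased rows still sum to one exactly, and
the package computes the largest ε for which all entries remain
probabilities, the exact biased stationary state, and its first-order
perturbative approximation (accurate to O(ε²)).

On top of the chain sit a seeded trajectory simulator (each sampled
direction moves the centroid by a fixed 6 µm step per 20 s) and the
standard motility statistics: ensemble MSD, the diffusion curve
D(t) = ⟨r²⟩/4t, the Fürth persistent-random-walk fit

    ⟨r²(t)⟩ = 2v²[τt − τ²(1 − e^(−t/τ))],

the alignment ⟨cos φ⟩(t) with a gradient, the chemotaxis index (its
time average) with the across-cell spread, and split-handedness turn
statistics.

## Worked example

```
$ dictywalk simulate --cells 10000 --steps 180 --seed 1 -o run/
$ dictywalk analyze --input run/ -o stats/
{"v_um_per_min": 16.322, "tau_min": 0.713, "D_plateau_um2_per_min": 93.428, "ci": -0.0001}
```

Ten thousand cells tracked for one hour in a homogeneous medium: the
Fürth fit gives a speed of ~16.3 µm/min (below the 18 µm/min raw path
speed, because directions decorrelate between steps) and a persistence
time of ~0.7 min; the diffusion curve plateaus near 93 µm²/min
(≈ v²τ/2), and the chemotaxis index is zero within Monte-Carlo error —
unbiased motion.  With a gradient switched on:

```
$ dictywalk chemotaxis-scan --epsilons 0,0.01,0.02,0.03,0.04 --cells 2000 --steps 180 --seed 1 -o scan/
 epsilon  stationary_mean_cos       ci   ci_std
    0.00        -1.183691e-16 0.001832 0.098923
    0.01         4.547482e-02 0.043140 0.101215
    0.02         9.093233e-02 0.093344 0.099665
    0.03         1.363552e-01 0.138248 0.098144
    0.04         1.817263e-01 0.184364 0.098571
```

The chemotaxis index grows linearly with the coupling ε and agrees with
the analytic stationary alignment of the biased chain; the across-cell
spread (~0.1) shows random reorientation still competing with the drift
at these weak couplings.

The same functionality is available as a library
(`dictywalk.build_transition_matrix`, `solve_stationary`,
`build_perturbed_matrix`, `simulate`, `fit_furth`, ...); see
`docs/methods.md` for the model details and numerical conventions.

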