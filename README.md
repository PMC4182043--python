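# llgcrep

Network-based drug repositioning: predicting new drug–disease associations
by spreading known association labels over a graph of drug–disease pairs
with the **learning with local and global consistency (LLGC)** method.

## Who this is for

Computational drug-discovery groups who have (i) a set of known
drug–disease associations, (ii) drug–target and target–target interaction
networks, and (iii) biological similarity matrices — chemical-structure
similarity between drugs and phenotype similarity between diseases — and
want a ranked list of candidate novel indications, plus the network
diagnostics (topology statistics, node-removal reliability) to judge how
trustworthy the underlying association network is.

## The method

Given a tripartite network of drugs, diseases and targets:

1. **Similarity fusion.** Two topology similarities are derived from the
   association network — cosine-normalized shared-neighbor counts, and the
   Pearson correlation of shortest-path-length profiles in the fully
   integrated graph M4 — fused by a weighted geometric mean and blended
   linearly with the biological similarity:
   `Sim = λ·Sim_bio + (1−λ)·Sim_topo`.
2. **Graph relevance vectors.** Each pair ⟨d, s⟩ gets one score per network
   node: the drug's similarity row, the disease's similarity row, and per
   target the best similarity-transferred interaction evidence
   (`1` for a known drug–target edge, else `max_{d′ hits t} Sim(d, d′)`,
   maximized with the disease's contribution through its drugs).
3. **GIP features.** Pairs are compared through the Gaussian interaction
   profile kernel against the n known pairs,
   `K(p, i) = exp(−r‖v_p − v_i‖²)`, `r = n / Σᵢ‖vᵢ‖²`.
4. **Label spreading.** Feature distances pass through the power transform
   `T(d) = σ₀(d/σ₀)^γ` (fixed point at σ₀, sharpening locality) into a
   Gaussian weight matrix `W`; with `S = D^{−1/2} W D^{−1/2}` the labels
   iterate `F(t+1) = αSF(t) + (1−α)Y` to the closed form
   `F* ∝ (I − αS)^{−1}Y`. σ₀ is read off the sparse band of the pairwise
   distance histogram; the score `F[:,0] − F[:,1]` ranks all pairs.

The package also computes seven topology statistics of the nested
integrated networks M1–M4 (edges, diameter, characteristic path length,
global efficiency, mean degree, degree heterogeneity, clustering, and the
degree-share structure entropy normalized between the star-graph minimum
and the uniform maximum), node-removal reliability curves (random vs
hub-targeted), and repeated k-fold cross-validation with self-implemented
AUC/AUPR and strict masking of held-out associations.

Because the original curated dataset is not public, the package ships a
synthetic generator that plants therapeutic-area modules (block-structured
associations and module-correlated similarities), including a preset that
reproduces the published dataset's exact dimensions (203 drugs, 52
diseases, 192 targets, 609 associations, 668 drug–target interactions).

## Worked example

```sh
python examples/01_simulate_and_predict.py
```

```
network: 30 drugs, 15 diseases, 20 targets, 83 known associations

GIP kernel bandwidth r = 0.0619

top 5 novel candidates (higher score = stronger predicted association):
 rank drug_id disease_id      score
   18   DR001      DI010 -50.991697
   19   DR016      DI010 -51.572995
   20   DR010      DI013 -51.577384
   21   DR004      DI007 -51.592365
   23   DR028      DI013 -51.780144

5/5 top candidates fall inside a planted module (the ground truth the generator hid)
```

Scores are relative (the unknown class dominates the label mass, so raw
values are negative); only the ranking matters, and all five top novel
candidates land inside the modules the generator planted.  The other
examples profile network topology (`02`), reliability under node removal
(`03`) and cross-validated ranking quality (`04`) — e.g. `04` prints a
mean 10-fold CV AUC of 0.8701 with an AUPR 5.0× the random-ranking
baseline on the default planted network.

The same workflow is available from the shell:

```sh
llgcrep simulate --preset default --seed 1 --out data/
llgcrep predict --data data/ --out predictions/
llgcrep topology --data data/
llgcrep robustness --data data/ --mode random --reps 20 --seed 17
llgcrep evaluate --data data/ --k 10 --repeats 1 --seed 7 --out eval/
```

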