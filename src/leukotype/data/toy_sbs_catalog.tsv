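category	SynSig1	SynSig2	SynSig3	SynSig4	SynSig5
A[C>A]A	0.049785	0.003408	0.003408	0.002023	0.003409
A[C>A]C	0.017850	0.003378	0.003378	0.002016	0.003378
A[C>A]G	0.065152	0.003378	0.003378	0.002016	0.003378
A[C>A]T	0.026688	0.003378	0.003378	0.002016	0.003378
C[C>A]A	0.041531	0.003378	0.003378	0.002016	0.003378
C[C>A]C	0.024164	0.003378	0.003378	0.002016	0.003378
C[C>A]G	0.058619	0.003378	0.003378	0.002016	0.003378
C[C>A]T	0.053233	0.003378	0.003378	0.002016	0.003378
G[C>A]A	0.042934	0.003378	0.003378	0.002016	0.003378
G[C>A]C	0.005715	0.003378	0.003378	0.002016	0.003378
G[C>A]G	0.054739	0.003378	0.003378	0.002016	0.003378
G[C>A]T	0.038402	0.003378	0.003378	0.002016	0.003378
T[C>A]A	0.054630	0.003378	0.003378	0.002016	0.003378
T[C>A]C	0.029494	0.003378	0.003378	0.002016	0.003378
T[C>A]G	0.046885	0.003378	0.003378	0.002016	0.003378
T[C>A]T	0.119939	0.003378	0.003378	0.002016	0.003378
A[C>G]A	0.003378	0.088367	0.003378	0.002016	0.003378
A[C>G]C	0.003378	0.031277	0.003378	0.002016	0.003378
A[C>G]G	0.003378	0.041622	0.003378	0.002016	0.003378
A[C>G]T	0.003378	0.065033	0.003378	0.002016	0.003378
C[C>G]A	0.003378	0.096411	0.003378	0.002016	0.003378
C[C>G]C	0.003378	0.024304	0.003378	0.002016	0.003378
C[C>G]G	0.003378	0.025053	0.003378	0.002016	0.003378
C[C>G]T	0.003378	0.034073	0.003378	0.002016	0.003378
G[C>G]A	0.003378	0.021720	0.003378	0.002016	0.003378
G[C>G]C	0.003378	0.084467	0.003378	0.002016	0.003378
G[C>G]G	0.003378	0.029933	0.003378	0.002016	0.003378
G[C>G]T	0.003378	0.079609	0.003378	0.002016	0.003378
T[C>G]A	0.003378	0.029587	0.003378	0.002016	0.003378
T[C>G]C	0.003378	0.032385	0.003378	0.002016	0.003378
T[C>G]G	0.003378	0.035019	0.003378	0.002016	0.003378
T[C>G]T	0.003378	0.010870	0.003378	0.002016	0.003378
A[C>T]A	0.003378	0.003378	0.034729	0.002016	0.003378
A[C>T]C	0.003378	0.003378	0.028993	0.002016	0.003378
A[C>T]G	0.003378	0.003378	0.047540	0.002016	0.003378
A[C>T]T	0.003378	0.003378	0.038544	0.002016	0.003378
C[C>T]A	0.003378	0.003378	0.048327	0.002016	0.003378
C[C>T]C	0.003378	0.003378	0.072749	0.002016	0.003378
C[C>T]G	0.003378	0.003378	0.062444	0.002016	0.003378
C[C>T]T	0.003378	0.003378	0.038048	0.002016	0.003378
G[C>T]A	0.003378	0.003378	0.023960	0.002016	0.003378
G[C>T]C	0.003378	0.003378	0.024165	0.002016	0.003378
G[C>T]G	0.003378	0.003378	0.106733	0.002016	0.003378
G[C>T]T	0.003378	0.003378	0.051219	0.002016	0.003378
T[C>T]A	0.003378	0.003378	0.053297	0.002016	0.003378
T[C>T]C	0.003378	0.003378	0.029400	0.002016	0.003378
T[C>T]G	0.003378	0.003378	0.019789	0.002016	0.003378
T[C>T]T	0.003378	0.003378	0.049793	0.002016	0.003378
A[T>A]A	0.003378	0.003378	0.003378	0.028144	0.003378
A[T>A]C	0.003378	0.003378	0.003378	0.020547	0.003378
A[T>A]G	0.003378	0.003378	0.003378	0.023533	0.003378
A[T>A]T	0.003378	0.003378	0.003378	0.006969	0.003378
C[T>A]A	0.003378	0.003378	0.003378	0.022298	0.003378
C[T>A]C	0.003378	0.003378	0.003378	0.032122	0.003378
C[T>A]G	0.003378	0.003378	0.003378	0.069619	0.003378
C[T>A]T	0.003378	0.003378	0.003378	0.060688	0.003378
G[T>A]A	0.003378	0.003378	0.003378	0.006169	0.003378
G[T>A]C	0.003378	0.003378	0.003378	0.006305	0.003378
G[T>A]G	0.003378	0.003378	0.003378	0.014813	0.003378
G[T>A]T	0.003378	0.003378	0.003378	0.050259	0.003378
T[T>A]A	0.003378	0.003378	0.003378	0.015671	0.003378
T[T>A]C	0.003378	0.003378	0.003378	0.020456	0.003378
T[T>A]G	0.003378	0.003378	0.003378	0.009272	0.003378
T[T>A]T	0.003378	0.003378	0.003378	0.048621	0.003378
A[T>C]A	0.003378	0.003378	0.003378	0.039678	0.003378
A[T>C]C	0.003378	0.003378	0.003378	0.010158	0.003378
A[T>C]G	0.003378	0.003378	0.003378	0.016839	0.003378
A[T>C]T	0.003378	0.003378	0.003378	0.020520	0.003378
C[T>C]A	0.003378	0.003378	0.003378	0.050975	0.003378
C[T>C]C	0.003378	0.003378	0.003378	0.040025	0.003378
C[T>C]G	0.003378	0.003378	0.003378	0.010260	0.003378
C[T>C]T	0.003378	0.003378	0.003378	0.059028	0.003378
G[T>C]A	0.003378	0.003378	0.003378	0.020413	0.003378
G[T>C]C	0.003378	0.003378	0.003378	0.047680	0.003378
G[T>C]G	0.003378	0.003378	0.003378	0.010342	0.003378
G[T>C]T	0.003378	0.003378	0.003378	0.026315	0.003378
T[T>C]A	0.003378	0.003378	0.003378	0.008721	0.003378
T[T>C]C	0.003378	0.003378	0.003378	0.035547	0.003378
T[T>C]G	0.003378	0.003378	0.003378	0.035997	0.003378
T[T>C]T	0.003378	0.003378	0.003378	0.002985	0.003378
A[T>G]A	0.003378	0.003378	0.003378	0.002016	0.125188
A[T>G]C	0.003378	0.003378	0.003378	0.002016	0.045372
A[T>G]G	0.003378	0.003378	0.003378	0.002016	0.044405
A[T>G]T	0.003378	0.003378	0.003378	0.002016	0.030376
C[T>G]A	0.003378	0.003378	0.003378	0.002016	0.043275
C[T>G]C	0.003378	0.003378	0.003378	0.002016	0.055591
C[T>G]G	0.003378	0.003378	0.003378	0.002016	0.006179
C[T>G]T	0.003378	0.003378	0.003378	0.002016	0.051023
G[T>G]A	0.003378	0.003378	0.003378	0.002016	0.097501
G[T>G]C	0.003378	0.003378	0.003378	0.002016	0.053001
G[T>G]G	0.003378	0.003378	0.003378	0.002016	0.011269
G[T>G]T	0.003378	0.003378	0.003378	0.002016	0.027546
T[T>G]A	0.003378	0.003378	0.003378	0.002016	0.023944
T[T>G]C	0.003378	0.003378	0.003378	0.002016	0.034539
T[T>G]G	0.003378	0.003378	0.003378	0.002016	0.042618
T[T>G]T	0.003378	0.003378	0.003378	0.002016	0.037902
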