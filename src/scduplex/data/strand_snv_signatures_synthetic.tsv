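Context	DS	SS
A[C>A]A	0.012856095235049363	0.02764538114427913
A[C>A]C	0.029561270796508707	0.07571918351241894
A[C>A]G	0.007810559654962109	0.016426779123108543
A[C>A]T	0.003628850343518727	0.008364540429309831
C[C>A]A	0.005340633421132319	0.011662614172127479
C[C>A]C	0.016490053904426837	0.029468796477541262
C[C>A]G	0.010574066615615685	0.022105550127004426
C[C>A]T	0.00948326852166599	0.022823326199528114
G[C>A]A	0.015197356542203382	0.02051031001994817
G[C>A]C	0.010423027801543113	0.013523377147811195
G[C>A]G	0.022778630017342517	0.035287462918647525
G[C>A]T	0.012981482147018613	0.0341631252832962
T[C>A]A	0.029757740589022412	0.04225585549779262
T[C>A]C	0.03055029634959706	0.08236557259862683
T[C>A]G	0.007272777423563961	0.007797251279478977
T[C>A]T	0.009351815208548185	0.012483334308569941
A[C>G]A	0.002688348355055708	0.0019130220410711206
A[C>G]C	0.005810802739343559	0.007296065652072951
A[C>G]G	0.0075189476684348125	0.003707002259213417
A[C>G]T	0.008675812728313798	0.004399314287248471
C[C>G]A	0.003154387877172933	0.0023050414978454444
C[C>G]C	0.0012202594535988135	0.002287687143357966
C[C>G]G	0.0025239175644097885	0.0019492161640681277
C[C>G]T	0.010009660349982637	0.005633375889829741
G[C>G]A	0.004932233469584209	0.004127710125734321
G[C>G]C	0.005707573916041827	0.004224727387428453
G[C>G]G	0.019972374239245083	0.010364722907527374
G[C>G]T	0.0114741453195163	0.007524194959113777
T[C>G]A	0.0052717115805633995	0.0038672884079437595
T[C>G]C	0.0069491747733653525	0.004117907491087018
T[C>G]G	0.0016227927756961636	0.000737709296153985
T[C>G]T	0.002624813599189231	0.0011905974002407067
A[C>T]A	0.008464955947768117	0.006903329176621597
A[C>T]C	0.007218474019431308	0.01623808662312566
A[C>T]G	0.01253119065750196	0.015547993869677243
A[C>T]T	0.00597741435503367	0.0046270830266943435
C[C>T]A	0.00869644279404123	0.01090764962266268
C[C>T]C	0.012952388029136237	0.010862533598063148
C[C>T]G	0.009269669258483108	0.02045519967150139
C[C>T]T	0.006785992805905026	0.007972486064514173
G[C>T]A	0.014851643258512081	0.009249248767577151
G[C>T]C	0.00584207781847844	0.0047795905469437076
G[C>T]G	0.022332224484831978	0.015387677434033412
G[C>T]T	0.00818718337594463	0.0076278145314923294
T[C>T]A	0.003915086302714317	0.005547337999109052
T[C>T]C	0.016616532692716776	0.008654879388023028
T[C>T]G	0.01098680523618243	0.016321529215432333
T[C>T]T	0.028513519378386407	0.02283730846954065
A[T>A]A	0.006835789726866381	0.0037757068907845748
A[T>A]C	0.004840328090593113	0.006040034733117769
A[T>A]G	0.003922543970387828	0.0032927092058462172
A[T>A]T	0.0033818454622362984	0.002724472247155046
C[T>A]A	0.002325989400191416	0.0017143021081752173
C[T>A]C	0.009281550034539277	0.008539738145272122
C[T>A]G	0.010473981760068564	0.006909507750824965
C[T>A]T	0.0038903990145432352	0.001954282668187818
G[T>A]A	0.004279431340608687	0.002826897654055435
G[T>A]C	0.010351574548791442	0.004758536802305895
G[T>A]G	0.016367054148286528	0.008344473128172854
G[T>A]T	0.010583563262501062	0.00540027915302117
T[T>A]A	0.019140891233341138	0.010270594897602247
T[T>A]C	0.00822844892256283	0.005830993420592567
T[T>A]G	0.013687776171758693	0.008703142811986194
T[T>A]T	0.006009357514984536	0.0032540594066255858
A[T>C]A	0.019228242966685665	0.01185098923794933
A[T>C]C	0.007626312633837792	0.003335879634715696
A[T>C]G	0.012358619023953884	0.007002789237854251
A[T>C]T	0.008367128555953809	0.006871270074858915
C[T>C]A	0.01317582108725832	0.006598867141134324
C[T>C]C	0.004020679188826104	0.0019909541837524894
C[T>C]G	0.012923625625438962	0.006203040062618922
C[T>C]T	0.03169099284901411	0.014353116168429419
G[T>C]A	0.019983476737332227	0.013696331961542177
G[T>C]C	0.01443406602469209	0.006219794106428653
G[T>C]G	0.031634230781596696	0.017509718441879263
G[T>C]T	0.005041285313510831	0.006172601438870805
T[T>C]A	0.00339296858131009	0.001932953630325104
T[T>C]C	0.0070529018915951956	0.010019857246285452
T[T>C]G	0.0032444137539225965	0.0032895584413613075
T[T>C]T	0.0010745377586364256	0.0008275259213665349
A[T>G]A	0.011318270665765318	0.0056323203451086505
A[T>G]C	0.0076027144414726605	0.004749321286147473
A[T>G]G	0.010337189794033648	0.00692283449364227
A[T>G]T	0.006052882210971344	0.007821926331883063
C[T>G]A	0.008250069169568884	0.00381678264205002
C[T>G]C	0.0064531664406884785	0.002832595134036309
C[T>G]G	0.012560744326376563	0.005939896796682511
C[T>G]T	0.0036888943764516384	0.002636378125384182
G[T>G]A	0.0036724908446477823	0.002081219907412997
G[T>G]C	0.007756905631163854	0.003772692696846731
G[T>G]G	0.008301946126944352	0.003641236187283876
G[T>G]T	0.019366082369059023	0.00920079609683112
T[T>G]A	0.003004318504096692	0.005479243623999837
T[T>G]C	0.025629932692831224	0.011122295645554203
T[T>G]G	0.015173171502434269	0.006650443078886872
T[T>G]T	0.004624912131368169	0.003317248500713945
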