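17
1-(1H-pyrrol-3-yl)ethanol, idealized placeholder geometry (synthetic; MMFF94-relaxed, not an optimized ab initio structure)
C       0.962519685703     0.850795733692     0.244297492781
N       2.274225861939     0.460318974196     0.171593198212
C       2.343067541438    -0.803012089169    -0.349167861168
C       1.059250032958    -1.224194589351    -0.610632716891
C       0.167718049442    -0.179384441831    -0.230615484792
C      -1.328837955232    -0.206915001921    -0.346848861296
C      -2.033314436755     0.116820195583     0.964979502049
O      -1.782716389906     0.710540468236    -1.342082197830
H       0.705180880101     1.827098852556     0.633616229297
H       3.068526889160     1.019317256656     0.456207775644
H       3.296763475680    -1.293127355273    -0.492385961277
H       0.787290823301    -2.183194186050    -1.034152527369
H      -3.119528034059     0.046868194253     0.840348851800
H      -1.823379580949     1.142640618160     1.288798008893
H      -1.647655522321    -1.204336259507    -0.671063807485
H      -1.728323521564    -0.567156502914     1.763556689484
H      -1.200787798936     1.486920132683    -1.286448330049
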