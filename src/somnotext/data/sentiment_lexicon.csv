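word,polarity,subjectivity
good,0.7,0.6
great,0.8,0.75
happy,0.8,1.0
love,0.5,0.6
loved,0.7,0.8
awesome,1.0,1.0
nice,0.6,1.0
fun,0.3,0.2
best,1.0,0.3
amazing,0.6,0.9
excited,0.375,0.75
beautiful,0.85,1.0
glad,0.5,1.0
win,0.8,0.4
sweet,0.35,0.65
cool,0.35,0.65
perfect,1.0,1.0
wonderful,1.0,1.0
thanks,0.2,0.2
proud,0.8,0.8
relaxed,0.4,0.6
rested,0.5,0.6
fresh,0.3,0.5
okay,0.2,0.5
fine,0.42,0.58
interesting,0.5,0.5
bad,-0.7,0.67
sad,-0.5,1.0
tired,-0.4,0.8
sleepy,-0.3,0.7
awful,-1.0,1.0
terrible,-1.0,1.0
hate,-0.8,0.9
hated,-0.9,0.9
worst,-1.0,1.0
sick,-0.7,0.9
angry,-0.5,1.0
bored,-0.5,1.0
boring,-0.6,1.0
stressed,-0.6,0.9
exhausted,-0.6,0.9
annoying,-0.6,0.9
ugly,-0.7,0.9
lonely,-0.4,0.8
mad,-0.6,0.9
cry,-0.5,0.8
crying,-0.5,0.8
fail,-0.6,0.7
failed,-0.7,0.7
miserable,-1.0,1.0
worried,-0.3,0.6
gloomy,-0.5,0.8
grumpy,-0.6,0.9
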